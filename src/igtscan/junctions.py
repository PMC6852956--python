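"""Insertion-junction flanks and microhomology scoring.

A microhomology is a run of identical nucleotides immediately adjacent to
an insertion's fusion point, shared between the recipient flank and the
donor sequence flanking the source interval.  Matching is anchored at the
fusion point (a suffix match on the upstream side, a prefix match on the
downstream side); the ambiguous base N never matches.  Flanks of insertions
that integrated in reverse orientation are compared after
reverse-complementing (and swapping) the donor flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import GenomeRecord, revcomp

DEFAULT_WINDOW = 10
MAX_WINDOW = 50


@dataclass
class JunctionContext:
    """Flanking sequences around one insertion breakpoint (all 5'->3' on
    the insertion's strand)."""

    insertion_id: str
    recipient_upstream: str
    recipient_downstream: str
    donor_upstream: str
    donor_downstream: str
    window: int
    truncated: bool = False  # a recipient flank was clipped at a sequence end


def _fetch_flank(rec: GenomeRecord, start: int, end: int) -> tuple[str, bool]:
    """[start, end) with circular wrap; clipped (and flagged) at the ends of
    linear sequences."""
    if rec.circular:
        return rec.fetch(start, end), False
    s, e = max(0, start), min(len(rec), end)
    return rec.sequence[s:e], (s != start or e != end)


def extract_flanks(recipient: GenomeRecord, insertion: tuple[int, int],
                   donor: GenomeRecord, source: tuple[int, int],
                   window: int = DEFAULT_WINDOW, orientation: str = "positive",
                   insertion_id: str = "") -> JunctionContext:
    """Extract the four flank strings around one insertion junction.

    Recipient flanks sit immediately outside the insertion interval; donor
    flanks sit immediately outside the source interval.  For a
    reverse-orientation insertion the donor flanks are reverse-complemented
    and swapped so all four strings read 5'->3' on the insertion's strand.
    """
    if not (0 < window <= MAX_WINDOW):
        raise ValueError(f"window must be in (0, {MAX_WINDOW}]")
    istart, iend = insertion
    sstart, send = source
    r_up, t1 = _fetch_flank(recipient, istart - window, istart)
    r_down, t2 = _fetch_flank(recipient, iend, iend + window)
    d_up, t3 = _fetch_flank(donor, sstart - window, sstart)
    d_down, t4 = _fetch_flank(donor, send, send + window)
    if orientation == "reverse":
        d_up, d_down = revcomp(d_down), revcomp(d_up)
    return JunctionContext(insertion_id, r_up, r_down, d_up, d_down, window,
                           truncated=t1 or t2 or t3 or t4)


def _anchored_match(a: str, b: str, side: str) -> int:
    if side == "upstream":       # both strings end at the fusion point
        a, b = a[::-1], b[::-1]
    elif side != "downstream":   # both strings start at the fusion point
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def microhomology_length(donor_flank: str, recipient_flank: str, side: str) -> int:
    """Length of the maximal exact match anchored at the fusion point
    between a donor flank and the corresponding recipient flank."""
    return _anchored_match(donor_flank, recipient_flank, side)


def score_junction(context: JunctionContext) -> tuple[int, int]:
    """(upstream, downstream) microhomology lengths of one junction."""
    return (microhomology_length(context.donor_upstream, context.recipient_upstream,
                                 "upstream"),
            microhomology_length(context.donor_downstream, context.recipient_downstream,
                                 "downstream"))


def shared_flank_across_species(contexts: Sequence[JunctionContext]) -> tuple[int, int]:
    """Per side, the maximal fusion-point-anchored recipient flank length
    identical across all species' contexts for one homologous insertion."""
    if len(contexts) < 2:
        raise ValueError("need at least two contexts to compare across species")
    up = min(_anchored_match(contexts[0].recipient_upstream, c.recipient_upstream,
                             "upstream") for c in contexts[1:])
    down = min(_anchored_match(contexts[0].recipient_downstream, c.recipient_downstream,
                               "downstream") for c in contexts[1:])
    window = min(c.window for c in contexts)
    return (min(up, window), min(down, window))
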