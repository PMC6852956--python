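"""Nuclear-derived repeats in the mitogenome and exact-repeat finding.

Repeat classification assigns mitogenome intervals to the best-scoring
element of a labelled repeat library (seven classes: copia, gypsy,
unclassified LTR retrotransposon, TE, simple repeat, low complexity,
unspecified), with overlaps resolved by score and then by a fixed class
priority.  Repeat thresholds are looser than the transfer presets
(identity >= 0.80, length >= 50 bp) because repeats diverge faster than
recent insertions.

``repeat_match`` reports all maximal exact repeated pairs of a sequence at
or above a minimum length (a repeat-match analog): maximal means the pair
can be extended neither left nor right; tandem pairs have period no larger
than their length; with ``forward_only=False`` reverse-complement
(palindromic) pairs are reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import GenomeRecord, revcomp
from .search import SearchParams, TransferHit, search, union_length

REPEAT_CLASS_PRIORITY = ("copia", "gypsy", "LTR_retro_unclassified", "TE",
                         "simple_repeat", "low_complexity", "unspecified")


@dataclass
class RepeatAnnotation:
    seq_id: str
    start: int
    end: int
    repeat_class: str
    library_element: str
    identity: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExactRepeat:
    """A maximal exact repeated pair at forward positions p1 < p2."""

    p1: int
    p2: int
    length: int
    tandem: bool
    palindromic: bool = False


def repeat_search_params(min_identity: float = 0.80, min_length: int = 50) -> SearchParams:
    return SearchParams(min_identity=min_identity, min_length=min_length,
                        evalue_report=1e-2)


@dataclass
class RepeatClassification:
    annotations: list[RepeatAnnotation]
    class_totals: dict[str, int]  # union bp per class (no double counting)


def classify_repeats(mitogenome: GenomeRecord,
                     library: Sequence[tuple[str, str, str]],
                     params: SearchParams | None = None) -> RepeatClassification:
    """Annotate the mitogenome with repeat-library homology.

    ``library`` holds (element name, class label, sequence) triples.  Each
    base is claimed by the hit with the highest score; ties fall to the
    higher-priority class, then the lower coordinate.  Per-class totals are
    the claimed base counts, so they sum to the union length of all
    annotated intervals.
    """
    params = params or repeat_search_params()
    hits: list[tuple[TransferHit, str, str]] = []
    for name, cls, seq in library:
        if cls not in REPEAT_CLASS_PRIORITY:
            raise ValueError(f"unknown repeat class {cls!r}")
        donor = GenomeRecord(name, mitogenome.species, "nuclear", seq)
        for h in search(donor, mitogenome, params):
            if h.aln_length >= params.min_length and h.identity >= params.min_identity:
                hits.append((h, name, cls))
    prio = {c: i for i, c in enumerate(REPEAT_CLASS_PRIORITY)}
    hits.sort(key=lambda t: (-t[0].score, prio[t[2]], t[0].recipient_start))
    n = len(mitogenome)
    owner = np.full(n, -1, dtype=int)
    annotations: list[RepeatAnnotation] = []
    for idx, (h, name, cls) in enumerate(hits):
        span = np.arange(h.recipient_start, h.recipient_end)
        free = span[owner[span] == -1]
        if len(free) == 0:
            continue
        owner[free] = idx
        # contiguous runs of newly claimed bases become annotations
        breaks = np.flatnonzero(np.diff(free) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(free) - 1]])
        for s_i, e_i in zip(starts, ends):
            annotations.append(RepeatAnnotation(
                mitogenome.id, int(free[s_i]), int(free[e_i]) + 1, cls, name,
                h.identity))
    totals = {c: 0 for c in REPEAT_CLASS_PRIORITY}
    for ann in annotations:
        totals[ann.repeat_class] += len(ann)
    annotations.sort(key=lambda a: (a.start, a.end))
    return RepeatClassification(annotations, totals)


def _maximal_pair(seq: str, i: int, j: int) -> tuple[int, int, int]:
    """Extend positions i < j of an exact match to a maximal pair; returns
    (p1, p2, length)."""
    n = len(seq)
    while i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
        i -= 1
        j -= 1
    l = 0
    while j + l < n and seq[i + l] == seq[j + l]:
        l += 1
    return i, j, l


def repeat_match(seq: str, min_length: int = 20, forward_only: bool = True,
                 tandem_only: bool = False) -> list[ExactRepeat]:
    """All maximal exact repeated pairs of length >= min_length.

    With ``forward_only=False``, maximal matches between the sequence and
    its reverse complement (palindromic pairs) are also reported, with both
    positions on the forward strand (p2 is the start of the
    reverse-complemented copy).
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    n = len(seq)
    found: set[tuple[int, int, int]] = set()
    positions: dict[str, list[int]] = {}
    k = min_length
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    for pos_list in positions.values():
        if len(pos_list) < 2:
            continue
        for a in range(len(pos_list)):
            for b in range(a + 1, len(pos_list)):
                i, j = pos_list[a], pos_list[b]
                p1, p2, l = _maximal_pair(seq, i, j)
                if l >= min_length:
                    found.add((p1, p2, l))
    out = [ExactRepeat(p1, p2, l, tandem=(p2 - p1 <= l)) for p1, p2, l in found]

    if not forward_only:
        rc = revcomp(seq)
        rc_positions: dict[str, list[int]] = {}
        for j in range(n - k + 1):
            rc_positions.setdefault(rc[j : j + k], []).append(j)
        pal_found: set[tuple[int, int, int]] = set()
        for kmer, fwd_list in positions.items():
            for i in fwd_list:
                for j in rc_positions.get(kmer, ()):  # match seq[i:] vs rc[j:]
                    p1, p2, l = _maximal_cross_pair(seq, rc, i, j)
                    if l < min_length:
                        continue
                    f2 = n - p2 - l  # start of the rc copy on the forward strand
                    a, b = sorted((p1, f2))
                    pal_found.add((a, b, l))
        out.extend(ExactRepeat(a, b, l, tandem=(b - a <= l), palindromic=True)
                   for a, b, l in pal_found)

    if tandem_only:
        out = [r for r in out if r.tandem]
    out.sort(key=lambda r: (r.p1, r.p2, r.length, r.palindromic))
    return out


def _maximal_cross_pair(s: str, t: str, i: int, j: int) -> tuple[int, int, int]:
    """Maximal common extension of s[i:] vs t[j:] (also leftward)."""
    while i > 0 and j > 0 and s[i - 1] == t[j - 1]:
        i -= 1
        j -= 1
    l = 0
    n, m = len(s), len(t)
    while i + l < n and j + l < m and s[i + l] == t[j + l]:
        l += 1
    return i, j, l


def linear_regression_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, R^2)
    with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(res.slope), float(res.intercept), r2
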