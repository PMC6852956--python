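"""Seed-and-extend nucleotide homology search between genome compartments.

Exact k-mer seeds on both strands are extended without gaps under an
x-drop criterion and scored with match/mismatch scores; significance uses
the Karlin-Altschul formula E = kappa * m * n * exp(-lambda * score).
Two filter presets reproduce the thresholds used for organelle-to-nucleus
insertions (>=100 bp at >=95% identity, E <= 1e-5) and for plastid
insertions into the mitogenome (>=50 bp, identity > 95%, donor coverage
> 90%).  Hits are reported on the forward strand of both sequences with an
orientation flag; circular donors are searched across the origin and
duplicate hits collapsed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core_io import GenomeRecord, GenomeSet

_BASE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BASE[ord(_c)] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: donor compartment -> recipient compartment -> direction label
_ABBR = {"nuclear": "nu", "mitochondrial": "mt", "chloroplast": "cp"}
DIRECTIONS = ("cp_to_nu", "mt_to_nu", "cp_to_mt", "nu_to_mt", "nu_to_cp", "mt_to_cp")


def direction_label(donor_compartment: str, recipient_compartment: str) -> str:
    return f"{_ABBR[donor_compartment]}_to_{_ABBR[recipient_compartment]}"


@dataclass
class SearchParams:
    """Scoring, seeding and filtering parameters for the homology search."""

    k: int = 12
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    lam: float = 1.33
    kappa: float = 0.621
    evalue_max: float = 1e-5
    min_length: int = 100
    min_identity: float = 0.95
    mtpt_min_length: int = 50
    mtpt_min_identity: float = 0.95   # strict >
    mtpt_min_coverage: float = 0.90   # strict >, donor (query) coverage
    cluster_gap: int = 500
    evalue_report: float = 1e-3       # coarse pre-filter applied by search()

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < self.k:
            raise ValueError("min_length must be >= seed length k")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")


@dataclass
class TransferHit:
    """One filtered homology match between a donor and a recipient genome.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; on a circular donor ``donor_end`` may exceed the donor length,
    meaning the match wraps the origin.
    """

    donor_seq: str
    donor_start: int
    donor_end: int
    recipient_seq: str
    recipient_start: int
    recipient_end: int
    orientation: str          # "positive" | "reverse"
    identity: float
    aln_length: int
    score: int
    evalue: float
    direction: str = ""

    @property
    def recipient_interval(self) -> tuple[int, int]:
        return (self.recipient_start, self.recipient_end)

    @property
    def donor_interval(self) -> tuple[int, int]:
        return (self.donor_start, self.donor_end)


@dataclass
class MergedInterval:
    """A recipient interval formed by merging nearby same-direction hits."""

    recipient_seq: str
    start: int
    end: int
    direction: str
    orientation: str
    hit_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DirectionSummary:
    species: str
    direction: str
    total_length_kb: float
    n_segments: int


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (uint8)."""
    return _BASE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer codes of every k-window; windows containing N are
    flagged invalid."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    valid = (win != 4).all(axis=1)
    return codes, valid


def compute_evalue(score: int, m: int, n: int, params: SearchParams) -> float:
    """Karlin-Altschul expectation for an ungapped score on sequences of
    lengths m and n."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return params.kappa * m * n * math.exp(-params.lam * score)


def _extend(darr: np.ndarray, rarr: np.ndarray, dpos: int, rpos: int,
            k: int, params: SearchParams, dlo: int, dhi: int) -> tuple[int, int, int, int, int, int]:
    """Ungapped x-drop extension of an exact k-mer seed.

    Returns (dstart, dend, rstart, rend, matches, score) in the coordinate
    system of ``darr``/``rarr``.  ``dlo``/``dhi`` bound the donor-side
    extension (used to cap circular-donor hits at one full turn).
    """
    match, mismatch, xdrop = params.match_score, params.mismatch_score, params.xdrop
    score = k * match
    matches = k
    # right
    best, cur = score, score
    best_d, best_r, best_m = dpos + k, rpos + k, matches
    i, j, m = dpos + k, rpos + k, matches
    while i < dhi and j < len(rarr):
        a, b = darr[i], rarr[j]
        if a == b and a != 4:
            cur += match
            m += 1
        else:
            cur += mismatch
        i += 1
        j += 1
        if cur > best:
            best, best_d, best_r, best_m = cur, i, j, m
        elif best - cur > xdrop:
            break
    score, matches = best, best_m
    dend, rend = best_d, best_r
    # left
    best, cur = score, score
    best_d, best_r, best_m = dpos, rpos, matches
    i, j, m = dpos - 1, rpos - 1, matches
    while i >= dlo and j >= 0:
        a, b = darr[i], rarr[j]
        if a == b and a != 4:
            cur += match
            m += 1
        else:
            cur += mismatch
        if cur > best:
            best, best_d, best_r, best_m = cur, i, j, m
        elif best - cur > xdrop:
            break
        i -= 1
        j -= 1
    return best_d, dend, best_r, rend, best_m, best


def _match_pairs(d_codes: np.ndarray, d_valid: np.ndarray,
                 r_codes: np.ndarray, r_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (donor_pos, recipient_pos) pairs with equal k-mer codes."""
    d_idx = np.flatnonzero(d_valid)
    r_idx = np.flatnonzero(r_valid)
    if len(d_idx) == 0 or len(r_idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rc = r_codes[r_idx]
    order = np.argsort(rc, kind="stable")
    rc_sorted = rc[order]
    r_sorted_pos = r_idx[order]
    dc = d_codes[d_idx]
    left = np.searchsorted(rc_sorted, dc, side="left")
    right = np.searchsorted(rc_sorted, dc, side="right")
    counts = right - left
    keep = counts > 0
    if not keep.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d_rep = np.repeat(d_idx[keep], counts[keep])
    # offsets into rc_sorted for each expanded pair
    starts = np.repeat(left[keep], counts[keep])
    within = np.arange(len(d_rep)) - np.repeat(
        np.cumsum(counts[keep]) - counts[keep], counts[keep])
    r_rep = r_sorted_pos[starts + within]
    return d_rep, r_rep


def search(donor: GenomeRecord, recipient: GenomeRecord,
           params: SearchParams | None = None) -> list[TransferHit]:
    """Find homologous segments of ``donor`` in ``recipient``.

    Both strands of the donor are seeded; hits are reported on the forward
    strands with an orientation flag, filtered only by a coarse E-value
    ceiling (apply :func:`filter_hits` for the analysis presets).
    """
    params = params or SearchParams()
    k = params.k
    if len(donor) < k or len(recipient) < k:
        return []
    L = len(donor)
    rarr = encode(recipient.sequence)
    r_codes, r_valid = _kmer_codes(rarr, k)
    direction = direction_label(donor.compartment, recipient.compartment)

    best: dict[tuple, TransferHit] = {}
    for orientation in ("positive", "reverse"):
        base = encode(donor.sequence)
        if orientation == "reverse":
            base = _COMP[base[::-1]]
        if donor.circular:
            darr = np.concatenate([base, base, base])
            seed_arr = base if L < k else np.concatenate([base, base[: k - 1]])
            offset = L  # seed positions are shifted into the middle copy
        else:
            darr = base
            seed_arr = base
            offset = 0
        d_codes, d_valid = _kmer_codes(seed_arr, k)
        d_pos, r_pos = _match_pairs(d_codes, d_valid, r_codes, r_valid)
        if len(d_pos) == 0:
            continue
        diag = r_pos - d_pos
        order = np.lexsort((d_pos, diag))
        d_pos, r_pos, diag = d_pos[order], r_pos[order], diag[order]
        covered_until: dict[int, int] = {}
        max_turn = L  # cap circular hits at one full turn
        for dp, rp, dg in zip(d_pos.tolist(), r_pos.tolist(), diag.tolist()):
            if dp + k <= covered_until.get(dg, -1):
                continue
            dp_eff = dp + offset
            if donor.circular:
                dlo = max(0, dp_eff + k - max_turn)
                dhi = min(len(darr), dp_eff + max_turn)
            else:
                dlo, dhi = 0, len(darr)
            ds, de, rs, re_, matches, score = _extend(
                darr, rarr, dp_eff, rp, k, params, dlo, dhi)
            covered_until[dg] = de - offset
            length = de - ds
            ev = compute_evalue(score, L, len(recipient), params)
            if ev > params.evalue_report:
                continue
            # map donor coords back to forward strand of the stored sequence
            ods, ode = ds - offset, de - offset
            if orientation == "reverse":
                fds, fde = L - ode, L - ods
            else:
                fds, fde = ods, ode
            if donor.circular:
                shift = fds % L - fds
                fds, fde = fds + shift, fde + shift
            key = (fds, fde, rs, re_, orientation)
            hit = TransferHit(
                donor_seq=donor.id, donor_start=fds, donor_end=fde,
                recipient_seq=recipient.id, recipient_start=rs, recipient_end=re_,
                orientation=orientation, identity=matches / length,
                aln_length=length, score=score, evalue=ev, direction=direction)
            prev = best.get(key)
            if prev is None or hit.score > prev.score:
                best[key] = hit
    hits = sorted(best.values(),
                  key=lambda h: (h.recipient_seq, h.recipient_start, h.recipient_end,
                                 h.donor_start, h.orientation))
    return hits


def classify_orientation(donor_pair: tuple[int, int],
                         recipient_pair: tuple[int, int]) -> str:
    """Orientation of a match given coordinate pairs in alignment order:
    positive when both pairs increase together, reverse otherwise."""
    d = donor_pair[1] - donor_pair[0]
    r = recipient_pair[1] - recipient_pair[0]
    return "positive" if (d > 0) == (r > 0) else "reverse"


def filter_hits(hits: Iterable[TransferHit], preset: str = "norg",
                params: SearchParams | None = None,
                query_lengths: dict[str, int] | None = None) -> list[TransferHit]:
    """Apply an analysis preset.

    ``norg``: length >= 100, identity >= 95%, E <= 1e-5 (organelle-to-nucleus
    insertions).  ``mtpt``: length >= 50, identity > 95%, donor (query)
    coverage > 90%; requires ``query_lengths`` mapping donor ids to their
    full lengths.
    """
    params = params or SearchParams()
    out = []
    if preset == "norg":
        for h in hits:
            if (h.aln_length >= params.min_length
                    and h.identity >= params.min_identity
                    and h.evalue <= params.evalue_max):
                out.append(h)
    elif preset == "mtpt":
        if query_lengths is None:
            raise ValueError("mtpt preset requires query_lengths for coverage")
        for h in hits:
            qlen = query_lengths[h.donor_seq]
            coverage = (h.donor_end - h.donor_start) / qlen
            if (h.aln_length >= params.mtpt_min_length
                    and h.identity > params.mtpt_min_identity
                    and coverage > params.mtpt_min_coverage):
                out.append(h)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return out


def merge_hits(hits: Sequence[TransferHit], cluster_gap: int = 500) -> list[MergedInterval]:
    """Merge recipient intervals that overlap or lie closer than
    ``cluster_gap``, within one (recipient, direction, orientation) group.

    Hits of opposite orientation are never merged.
    """
    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, h in enumerate(hits):
        groups.setdefault((h.recipient_seq, h.direction, h.orientation), []).append(i)
    merged: list[MergedInterval] = []
    for (rid, direction, orientation), idxs in sorted(groups.items()):
        idxs.sort(key=lambda i: (hits[i].recipient_start, hits[i].recipient_end))
        cur: MergedInterval | None = None
        for i in idxs:
            h = hits[i]
            if cur is not None and h.recipient_start < cur.end + cluster_gap:
                cur.end = max(cur.end, h.recipient_end)
                cur.hit_indices.append(i)
            else:
                cur = MergedInterval(rid, h.recipient_start, h.recipient_end,
                                     direction, orientation, [i])
                merged.append(cur)
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total covered length of a set of half-open intervals (no double
    counting of overlaps)."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def tabulate_directions(genome_set: GenomeSet,
                        hits: Sequence[TransferHit]) -> list[DirectionSummary]:
    """Per species x direction union length (kb) of merged recipient
    intervals.  All six directions are always reported (zeros allowed)."""
    rec_species = {r.id: r.species for r in genome_set.records}
    by_key: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for h in hits:
        sp = rec_species[h.recipient_seq]
        by_key.setdefault((sp, h.direction), {}).setdefault(
            h.recipient_seq, []).append(h.recipient_interval)
    out = []
    for sp in genome_set.species_list:
        for direction in DIRECTIONS:
            per_seq = by_key.get((sp, direction), {})
            total = sum(union_length(ivs) for ivs in per_seq.values())
            nseg = sum(
                len(merge_hits([h for h in hits
                                if h.direction == direction and h.recipient_seq == rid],
                               cluster_gap=0))
                for rid in per_seq)
            out.append(DirectionSummary(sp, direction, total / 1000.0, nseg))
    return out


def direction_ratio(summaries: Sequence[DirectionSummary], species: str,
                    numerator: str, denominator: str) -> float:
    """Ratio of two direction totals for one species, rounded to 2
    decimals; NaN when the denominator is zero."""
    totals = {(s.species, s.direction): s.total_length_kb for s in summaries}
    num = totals.get((species, numerator), 0.0)
    den = totals.get((species, denominator), 0.0)
    if den == 0:
        return float("nan")
    return round(num / den, 2)


_PAIRS = {
    "mt_to_nu": ("mitochondrial", "nuclear"),
    "cp_to_nu": ("chloroplast", "nuclear"),
    "cp_to_mt": ("chloroplast", "mitochondrial"),
    "nu_to_mt": ("nuclear", "mitochondrial"),
    "nu_to_cp": ("nuclear", "chloroplast"),
    "mt_to_cp": ("mitochondrial", "chloroplast"),
}


def search_species(genome_set: GenomeSet, species: str,
                   directions: Sequence[str] = DIRECTIONS,
                   params: SearchParams | None = None,
                   preset: str = "norg") -> list[TransferHit]:
    """Run the search for every requested transfer direction within one
    species and return the preset-filtered hits."""
    params = params or SearchParams()
    hits: list[TransferHit] = []
    for direction in directions:
        donor_comp, recip_comp = _PAIRS[direction]
        for donor in genome_set.records_for(species, donor_comp):
            for recipient in genome_set.records_for(species, recip_comp):
                raw = search(donor, recipient, params)
                if preset == "mtpt":
                    qlens = {donor.id: len(donor)}
                    hits.extend(filter_hits(raw, "mtpt", params, qlens))
                else:
                    hits.extend(filter_hits(raw, "norg", params))
    return hits


def detect_mtpt(genome_set: GenomeSet, species: str,
                params: SearchParams | None = None) -> list[TransferHit]:
    """Plastid-insertion (mtpt) detection with each annotated chloroplast
    gene as the query against the mitogenome, using the mtpt preset
    (length >= 50, identity > 95%, query coverage > 90%)."""
    params = params or SearchParams()
    hits: list[TransferHit] = []
    for cp in genome_set.records_for(species, "chloroplast"):
        genes = [f for f in genome_set.features
                 if f.seq_id == cp.id and f.feature_type in ("gene", "tRNA", "rRNA")]
        for mt in genome_set.records_for(species, "mitochondrial"):
            for f in genes:
                query = GenomeRecord(f.name, species, "chloroplast",
                                     cp.fetch(f.start, f.end))
                raw = search(query, mt, params)
                for h in filter_hits(raw, "mtpt", params, {f.name: len(query)}):
                    # report donor coordinates on the plastome
                    hits.append(replace(h, donor_seq=cp.id,
                                        donor_start=h.donor_start + f.start,
                                        donor_end=h.donor_end + f.start,
                                        direction="cp_to_mt"))
    return hits


def percent_of_genome(total_length_kb: float, genome_size_mb: float) -> float:
    """Insertion load as a percentage of genome size (2-decimal report)."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return round(100.0 * (total_length_kb * 1000.0) / (genome_size_mb * 1e6), 2)
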