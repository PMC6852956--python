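"""Expression of organellar genes versus their nuclear copies.

An organellar gene and its nuclear copy typically differ at only a handful
of sites, so short reads are attributed using diagnostic SNPs: a read is
assigned to a copy only when it overlaps at least one diagnostic site and
carries that copy's allele at every overlapped site.  Reads overlapping no
site are removed as ambiguous; reads carrying a mixture of alleles are
counted as conflicting and excluded.  Expression is summarised by RPKM
(1e9 * count / (total mapped reads * length)), qPCR fold changes by
2^-ddCt, and the organellar component of mixed qPCR measurements by
OE = NOE - NE (floored at zero, flagged when the raw difference is
negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import revcomp


@dataclass
class DiagnosticSites:
    sites: list[tuple[int, str, str]]  # (offset, allele of copy A, allele of copy B)
    percent_divergence: float          # 100 * n_sites / length, 1-decimal report

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class GenePair:
    """An organellar gene and its equal-length nuclear homolog."""

    gene: str
    organellar_name: str
    organellar_seq: str
    nuclear_name: str
    nuclear_seq: str
    diagnostics: DiagnosticSites = field(init=False)

    def __post_init__(self) -> None:
        self.diagnostics = diagnostic_sites(self.organellar_seq, self.nuclear_seq)

    @property
    def aligned_length(self) -> int:
        return len(self.organellar_seq)


def diagnostic_sites(seq_a: str, seq_b: str) -> DiagnosticSites:
    """Mismatch offsets between two end-to-end-aligned copies, plus the
    percent divergence (1 decimal)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            "copies differ in length; align them first (substitution-only mode "
            "requires equal lengths)")
    sites = [(i, a, b) for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]
    pct = round(100.0 * len(sites) / len(seq_a), 1) if seq_a else 0.0
    return DiagnosticSites(sites, pct)


@dataclass
class Placement:
    read_name: str
    reference: str
    position: int     # 0-based start on the reference
    strand: str       # "+" | "-"
    mismatches: int


def _hamming_positions(read: str, ref: str, max_mismatches: int) -> list[tuple[int, int]]:
    out = []
    n, m = len(ref), len(read)
    for p in range(n - m + 1):
        mm = 0
        window = ref[p : p + m]
        for a, b in zip(read, window):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            out.append((p, mm))
    return out


def map_reads(reads: Sequence[tuple[str, str]], references: dict[str, str],
              max_mismatches: int = 2, seed_length: int = 20,
              both_strands: bool = True) -> list[Placement]:
    """All placements of each read on the references with at most
    ``max_mismatches`` substitutions.

    Candidate positions come from exact matching of pigeonhole read
    segments (max_mismatches + 1 non-overlapping seeds) followed by full
    Hamming verification, which finds every placement within the mismatch
    budget.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for rname, rseq in references.items():
        for p in range(len(rseq) - seed_length + 1):
            index.setdefault(rseq[p : p + seed_length], []).append((rname, p))
    placements: list[Placement] = []
    for name, seq in reads:
        for strand in ("+", "-") if both_strands else ("+",):
            oriented = seq if strand == "+" else revcomp(seq)
            n_seg = max_mismatches + 1
            seen: set[tuple[str, int]] = set()
            if len(oriented) < seed_length * n_seg:
                # short read: verify against every position directly
                for rname, rseq in references.items():
                    for p, mm in _hamming_positions(oriented, rseq, max_mismatches):
                        if (rname, p) not in seen:
                            seen.add((rname, p))
                            placements.append(Placement(name, rname, p, strand, mm))
                continue
            seg_len = len(oriented) // n_seg
            for si in range(n_seg):
                off = si * seg_len
                seed = oriented[off : off + seed_length]
                for rname, p in index.get(seed, ()):  # candidate anchor
                    start = p - off
                    rseq = references[rname]
                    if start < 0 or start + len(oriented) > len(rseq):
                        continue
                    if (rname, start) in seen:
                        continue
                    mm = sum(a != b for a, b in
                             zip(oriented, rseq[start : start + len(oriented)]))
                    if mm <= max_mismatches:
                        seen.add((rname, start))
                        placements.append(Placement(name, rname, start, strand, mm))
    placements.sort(key=lambda pl: (pl.read_name, pl.reference, pl.position, pl.strand))
    return placements


@dataclass
class AssignmentResult:
    assigned: dict[str, int]          # copy name -> read count
    assigned_reads: dict[str, str]    # read name -> copy name
    ambiguous_removed: int
    conflicting: int
    unplaced: int
    total_overlapping: int

    def check_partition(self) -> bool:
        return (sum(self.assigned.values()) + self.ambiguous_removed
                + self.conflicting == self.total_overlapping)


def assign_reads(placements: Sequence[Placement], pair: GenePair,
                 reads: Sequence[tuple[str, str]]) -> AssignmentResult:
    """Attribute reads to the organellar or nuclear copy of a pair using
    its diagnostic sites.

    A read is assigned to a copy iff it overlaps >=1 diagnostic site and
    matches that copy's allele at every overlapped site; reads overlapping
    no site are ambiguous (removed); reads with alleles from both copies
    (or neither) are conflicting (excluded).
    """
    read_seqs = dict(reads)
    by_read: dict[str, list[Placement]] = {}
    for pl in placements:
        by_read.setdefault(pl.read_name, []).append(pl)
    org, nuc = pair.organellar_name, pair.nuclear_name
    assigned = {org: 0, nuc: 0}
    assigned_reads: dict[str, str] = {}
    ambiguous = conflicting = unplaced = 0
    for rname, pls in by_read.items():
        best = min(pls, key=lambda pl: (pl.mismatches, pl.reference, pl.position))
        oriented = read_seqs[rname] if best.strand == "+" else revcomp(read_seqs[rname])
        votes: set[str] = set()
        overlapped = 0
        for off, a_org, a_nuc in pair.diagnostics.sites:
            rel = off - best.position
            if 0 <= rel < len(oriented):
                overlapped += 1
                base = oriented[rel]
                if base == a_org:
                    votes.add(org)
                elif base == a_nuc:
                    votes.add(nuc)
                else:
                    votes.add("neither")
        if overlapped == 0:
            ambiguous += 1
        elif votes == {org}:
            assigned[org] += 1
            assigned_reads[rname] = org
        elif votes == {nuc}:
            assigned[nuc] += 1
            assigned_reads[rname] = nuc
        else:
            conflicting += 1
    return AssignmentResult(assigned, assigned_reads, ambiguous, conflicting,
                            unplaced, len(by_read))


def reconcile_pairs(result_r1: dict[str, str], result_r2: dict[str, str],
                    ambiguous_r1: set[str], ambiguous_r2: set[str]) -> dict[str, str]:
    """Conservative mate reconciliation: a pair keeps an assignment only
    when the mates agree or one of them is ambiguous."""
    out: dict[str, str] = {}
    pairs = {n.rsplit("/", 1)[0] for n in
             list(result_r1) + list(result_r2) + list(ambiguous_r1) + list(ambiguous_r2)}
    for p in pairs:
        a1 = result_r1.get(f"{p}/1")
        a2 = result_r2.get(f"{p}/2")
        if a1 and a2:
            if a1 == a2:
                out[p] = a1
        elif a1 or a2:
            out[p] = a1 or a2
    return out


def rpkm(count: int, gene_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        return float("nan")
    return 1e9 * count / (total_mapped * gene_length_bp)


def fold_change_ddct(ct_target_treat: float, ct_ref_treat: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


@dataclass
class OrganellarExpression:
    value: float
    flagged_negative: bool


def organellar_expression(noe: float, ne: float) -> OrganellarExpression:
    """OE = NOE - NE (total minus nuclear-only expression), floored at
    zero with a flag when the raw difference is negative."""
    if noe < 0 or ne < 0:
        raise ValueError("expression values must be >= 0")
    raw = noe - ne
    return OrganellarExpression(max(raw, 0.0), flagged_negative=raw < 0)
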