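import math

import numpy as np
import pytest

from igtscan.core_io import revcomp
from igtscan.expression import (GenePair, Placement, assign_reads,
                                diagnostic_sites, fold_change_ddct, map_reads,
                                organellar_expression, rpkm)
from igtscan.simulate import (ReadSpec, mutate_sequence, random_cds, random_dna,
                              simulate_reads)

from conftest import binom_interval


def test_diagnostic_sites_published_divergences():
    rng = np.random.default_rng(0)
    a = random_dna(402, rng)
    b = list(a)
    for pos in (10, 60, 120, 200, 300, 390):  # six SNPs over 402 nt
        b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
    d = diagnostic_sites(a, "".join(b))
    assert len(d) == 6 and d.percent_divergence == 1.5
    a2 = random_dna(114, rng)
    b2 = list(a2)
    for pos in (3, 20, 40, 60, 80, 100, 110):  # seven SNPs over 114 nt
        b2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b2[pos]]
    d2 = diagnostic_sites(a2, "".join(b2))
    assert len(d2) == 7 and d2.percent_divergence == 6.1


def test_identical_copies_have_no_sites():
    d = diagnostic_sites("ACGT" * 50, "ACGT" * 50)
    assert len(d) == 0 and d.percent_divergence == 0.0


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="align"):
        diagnostic_sites("ACGT", "ACG")


def brute_placements(read, refs, max_mm):
    out = set()
    for strand in "+-":
        r = read if strand == "+" else revcomp(read)
        for name, ref in refs.items():
            for p in range(len(ref) - len(r) + 1):
                mm = sum(a != b for a, b in zip(r, ref[p:p + len(r)]))
                if mm <= max_mm:
                    out.add((name, p, strand, mm))
    return out


@pytest.mark.parametrize("seed", [1, 2])
def test_map_reads_equals_sliding_hamming_oracle(seed):
    rng = np.random.default_rng(seed)
    refs = {"a": random_dna(1500, rng), "b": random_dna(900, rng)}
    reads = []
    for i in range(30):
        name, ref = ("a", refs["a"]) if rng.random() < 0.5 else ("b", refs["b"])
        start = int(rng.integers(0, len(ref) - 125))
        r = mutate_sequence(ref[start:start + 125], 0.01, rng)
        if rng.random() < 0.5:
            r = revcomp(r)
        reads.append((f"r{i}", r))
    placements = map_reads(reads, refs, max_mismatches=2)
    got = {(pl.read_name, pl.reference, pl.position, pl.strand, pl.mismatches)
           for pl in placements}
    expected = set()
    for name, r in reads:
        for ref_name, p, strand, mm in brute_placements(r, refs, 2):
            expected.add((name, ref_name, p, strand, mm))
    assert got == expected


def test_read_from_shared_region_is_multi_mapped():
    rng = np.random.default_rng(3)
    shared = random_dna(300, rng)
    refs = {"org": shared + random_dna(200, rng), "nuc": shared + random_dna(200, rng)}
    read = shared[50:175]
    placements = map_reads([("r0", read)], refs)
    assert {pl.reference for pl in placements} >= {"org", "nuc"}


def _pair(rng, length=402, divergence=0.015):
    org = random_cds(length // 3, rng)
    nuc = mutate_sequence(org, divergence, rng)
    return GenePair("g", "g_org", org, "g_nuc", nuc)


def test_assignment_partition_and_perfect_specificity():
    rng = np.random.default_rng(4)
    pair = _pair(rng)
    reads = simulate_reads([("g_org", pair.organellar_seq), ("g_nuc", pair.nuclear_seq)],
                           [9.0, 1.0], 500, ReadSpec(error_rate=0.0), rng=5)
    placements = map_reads(reads.reads,
                           {"g_org": pair.organellar_seq, "g_nuc": pair.nuclear_seq})
    result = assign_reads(placements, pair, reads.reads)
    assert result.check_partition()
    # with zero sequencing error no read is ever assigned to the wrong copy
    for rname, copy in result.assigned_reads.items():
        assert rname.startswith(copy)
    # planted 9:1 expression recovered in the assigned counts
    n_assigned = sum(result.assigned.values())
    lo, hi = binom_interval(n_assigned, 0.9)
    assert lo <= result.assigned["g_org"] <= hi


def test_read_overlapping_no_site_is_ambiguous():
    rng = np.random.default_rng(6)
    org = random_dna(400, rng)
    nuc = org[:200] + mutate_sequence(org[200:], 0.05, rng)  # sites only in [200,400)
    pair = GenePair("g", "org", org, "nuc", nuc)
    read = org[10:135]  # identical region, overlaps zero sites
    placements = map_reads([("r0/1", read)], {"org": org, "nuc": nuc})
    result = assign_reads(placements, pair, [("r0/1", read)])
    assert result.ambiguous_removed == 1 and sum(result.assigned.values()) == 0


def test_single_site_with_organellar_allele_assigned_organellar():
    rng = np.random.default_rng(7)
    pair = _pair(rng)
    off, a_org, _ = pair.diagnostics.sites[0]
    start = max(0, off - 60)
    read = pair.organellar_seq[start:start + 125]
    placements = map_reads([("r0/1", read)],
                           {pair.organellar_name: pair.organellar_seq,
                            pair.nuclear_name: pair.nuclear_seq})
    result = assign_reads(placements, pair, [("r0/1", read)])
    assert result.assigned[pair.organellar_name] == 1


def test_ambiguity_grows_as_divergence_shrinks():
    fractions = []
    for divergence in (0.05, 0.02, 0.008, 0.003):
        rng = np.random.default_rng(8)
        pair = _pair(rng, length=600, divergence=divergence)
        reads = simulate_reads([("g_org", pair.organellar_seq),
                                ("g_nuc", pair.nuclear_seq)],
                               [1.0, 1.0], 300, ReadSpec(error_rate=0.0), rng=9)
        placements = map_reads(reads.reads, {"g_org": pair.organellar_seq,
                                             "g_nuc": pair.nuclear_seq})
        result = assign_reads(placements, pair, reads.reads)
        fractions.append(result.ambiguous_removed / result.total_overlapping)
    assert all(a <= b + 0.02 for a, b in zip(fractions, fractions[1:]))


def test_rpkm_formula_and_scale_invariance():
    assert rpkm(0, 1000, 10**6) == 0.0
    assert rpkm(10, 1000, 10**6) == 10.0
    assert rpkm(100, 500, 2_000_000) == rpkm(1000, 500, 20_000_000)
    assert math.isnan(rpkm(5, 1000, 0))


def test_pooled_rpkm_consistency():
    # computing from summed counts/totals equals the count-weighted combination
    c1, c2, t1, t2, L = 30, 50, 10**6, 3 * 10**6, 800
    pooled = rpkm(c1 + c2, L, t1 + t2)
    assert pooled == pytest.approx(1e9 * (c1 + c2) / ((t1 + t2) * L))


def test_fold_change_examples():
    assert fold_change_ddct(20, 18, 20, 18) == 1.0
    assert fold_change_ddct(19, 18, 20, 18) == 2.0
    assert fold_change_ddct(20, 18, 22, 18) == 4.0


def test_organellar_expression_floor_and_flag():
    assert organellar_expression(10, 4).value == 6
    assert organellar_expression(5, 5).value == 0
    neg = organellar_expression(3, 5)
    assert neg.value == 0 and neg.flagged_negative
    with pytest.raises(ValueError):
        organellar_expression(-1, 0)
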