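import math

import numpy as np
import pytest
from Bio import Align

from igtscan.core_io import GenomeRecord, revcomp
from igtscan.search import (DIRECTIONS, SearchParams, TransferHit,
                            classify_orientation, compute_evalue, direction_ratio,
                            filter_hits, merge_hits, percent_of_genome, search,
                            tabulate_directions, union_length)
from igtscan.simulate import mutate_sequence, random_dna

from conftest import bitmap_union_length


def _rec(seq, comp="mitochondrial", circular=False, id="don", species="sp"):
    return GenomeRecord(id, species, comp, seq, circular)


def _embed(rng, fragment, flank=3000):
    left = random_dna(flank, rng)
    right = random_dna(flank, rng)
    return left + fragment + right, flank


def test_verbatim_copy_gives_single_exact_hit():
    rng = np.random.default_rng(0)
    frag = random_dna(200, rng)
    donor = _rec(random_dna(1000, rng) + frag + random_dna(1000, rng))
    rseq, start = _embed(rng, frag)
    hits = search(donor, _rec(rseq, "nuclear", id="chr"), SearchParams())
    strong = [h for h in hits if h.aln_length >= 100]
    assert len(strong) == 1
    h = strong[0]
    assert h.identity == 1.0
    assert h.aln_length == 200
    assert h.orientation == "positive"
    assert (h.recipient_start, h.recipient_end) == (start, start + 200)
    assert (h.donor_start, h.donor_end) == (1000, 1200)


def test_reverse_complement_fragment_gives_reverse_hit():
    rng = np.random.default_rng(1)
    frag = random_dna(200, rng)
    donor = _rec(random_dna(500, rng) + frag + random_dna(500, rng))
    rseq, start = _embed(rng, revcomp(frag))
    hits = [h for h in search(donor, _rec(rseq, "nuclear", id="chr")) if h.aln_length >= 100]
    assert len(hits) == 1
    h = hits[0]
    assert h.orientation == "reverse"
    # chance flank matches may extend the hit by a few bases past the plant
    assert h.donor_start <= 500 and h.donor_end >= 700 and h.aln_length <= 220
    assert h.recipient_start <= start and h.recipient_end >= start + 200


def _dp_identity(a: str, b: str) -> float:
    """Full dynamic-programming alignment oracle for the planted pair."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = sum(1 for (s1, e1), (s2, e2) in zip(*aln.aligned)
                  for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    length = max(aln.shape[1], 1)
    return matches / length


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_mutated_fragment_identity_matches_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    frag = random_dna(600, rng)
    mutated = mutate_sequence(frag, 0.05, rng)
    donor = _rec(random_dna(800, rng) + frag + random_dna(800, rng))
    rseq, start = _embed(rng, mutated)
    hits = [h for h in search(donor, _rec(rseq, "nuclear", id="chr")) if h.aln_length >= 100]
    assert len(hits) == 1
    h = hits[0]
    planted_donor = donor.sequence[h.donor_start:h.donor_end]
    planted_recip = rseq[h.recipient_start:h.recipient_end]
    assert h.identity == pytest.approx(_dp_identity(planted_donor, planted_recip), abs=0.01)


def test_search_shorter_than_seed_returns_empty():
    assert search(_rec("ACGT"), _rec("ACGTACGTACGTACGT", "nuclear", id="chr")) == []


def test_circular_donor_wrap_hit_matches_doubled_oracle():
    rng = np.random.default_rng(5)
    mt = random_dna(4000, rng)
    donor = _rec(mt, circular=True)
    # fragment spanning the origin: last 120 + first 120 bases
    frag = mt[-120:] + mt[:120]
    rseq, start = _embed(rng, frag)
    hits = [h for h in search(donor, _rec(rseq, "nuclear", id="chr")) if h.aln_length >= 200]
    assert len(hits) == 1
    h = hits[0]
    assert 240 <= h.aln_length <= 260
    assert h.donor_start < 4000 < h.donor_end  # wraps the origin
    # oracle: the same fragment must align at the same place in the doubled sequence
    doubled = _rec(mt + mt, circular=False, id="don2")
    oh = [x for x in search(doubled, _rec(rseq, "nuclear", id="chr")) if x.aln_length >= 200]
    assert any(x.donor_start % 4000 == h.donor_start % 4000 for x in oh)


def test_search_symmetric_under_recipient_reverse_complement():
    rng = np.random.default_rng(6)
    frag = random_dna(300, rng)
    donor = _rec(random_dna(400, rng) + frag + random_dna(400, rng))
    rseq, _ = _embed(rng, frag, flank=1000)
    fwd = [h for h in search(donor, _rec(rseq, "nuclear", id="chr")) if h.aln_length >= 100]
    rev = [h for h in search(donor, _rec(revcomp(rseq), "nuclear", id="chr"))
           if h.aln_length >= 100]
    assert len(fwd) == len(rev) == 1
    assert fwd[0].orientation != rev[0].orientation
    assert fwd[0].aln_length == rev[0].aln_length


def test_evalue_formula_and_monotonicity():
    p = SearchParams()
    assert compute_evalue(1000, 10_000, 1_000_000, p) < 1e-200
    assert compute_evalue(50, 1000, 2000, p) == pytest.approx(
        2 * compute_evalue(50, 1000, 1000, p))
    assert compute_evalue(60, 1000, 1000, p) < compute_evalue(50, 1000, 1000, p)
    # 100-bp perfect match between 10 kb and 1 Mb sequences clears 1e-5
    e = 0.621 * 1e4 * 1e6 * math.exp(-1.33 * 100)
    assert compute_evalue(100, 10_000, 1_000_000, p) == pytest.approx(e)
    assert e < 1e-5


def _mk(length, identity, evalue=1e-10, ds=0, de=None):
    de = ds + length if de is None else de
    return TransferHit("q", ds, de, "s", 0, length, "positive", identity,
                       length, int(identity * length), evalue, "cp_to_mt")


def test_filter_presets():
    p = SearchParams()
    assert filter_hits([_mk(99, 1.0)], "norg", p) == []          # below 100 bp
    assert filter_hits([_mk(500, 0.94)], "norg", p) == []        # below identity
    assert len(filter_hits([_mk(100, 0.95)], "norg", p)) == 1    # inclusive bounds
    assert filter_hits([_mk(200, 0.96, evalue=1e-3)], "norg", p) == []
    mtpt_hit = _mk(60, 0.96, ds=0, de=60)
    assert len(filter_hits([mtpt_hit], "mtpt", p, {"q": 65})) == 1  # cov 0.92
    assert filter_hits([mtpt_hit], "mtpt", p, {"q": 70}) == []      # cov < 0.9 strict
    assert filter_hits([_mk(500, 0.94)], "mtpt", p, {"q": 500}) == []
    assert filter_hits([_mk(60, 0.95, de=60)], "mtpt", p, {"q": 60}) == []  # strict >


def test_merge_hits_examples():
    hits = [_mk(150, 1.0), _mk(150, 1.0)]
    hits[1].recipient_start, hits[1].recipient_end = 100, 250
    merged = merge_hits(hits, cluster_gap=500)
    assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 250)
    assert union_length([(0, 150), (100, 250)]) == 250
    far = [_mk(100, 1.0), _mk(100, 1.0)]
    far[1].recipient_start, far[1].recipient_end = 700, 800
    assert len(merge_hits(far, cluster_gap=500)) == 2


def test_opposite_orientations_never_merge():
    a, b = _mk(200, 1.0), _mk(200, 1.0)
    b.orientation = "reverse"
    b.recipient_start, b.recipient_end = 100, 300
    assert len(merge_hits([a, b], cluster_gap=500)) == 2


def test_union_length_matches_bitmap_oracle_and_is_order_invariant():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(1, 25))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 900))
            ivs.append((s, s + int(rng.integers(1, 120))))
        assert union_length(ivs) == bitmap_union_length(ivs, 2000)
        perm = [ivs[i] for i in rng.permutation(n)]
        assert union_length(perm) == union_length(ivs)
        # splitting an interval into abutting halves changes nothing
        s, e = ivs[0]
        mid = (s + e) // 2
        if mid > s:
            assert union_length([(s, mid), (mid, e)] + ivs[1:]) == union_length(ivs)


def test_classify_orientation():
    assert classify_orientation((100, 300), (5000, 5200)) == "positive"
    assert classify_orientation((100, 300), (5200, 5000)) == "reverse"
    assert classify_orientation((300, 100), (5200, 5000)) == "positive"


def test_tabulate_zero_hits_reports_all_directions(genome_set):
    summaries = tabulate_directions(genome_set, [])
    per_sp = [s for s in summaries if s.species == genome_set.species_list[0]]
    assert sorted(s.direction for s in per_sp) == sorted(DIRECTIONS)
    assert all(s.total_length_kb == 0.0 for s in summaries)


def test_direction_ratio_published_arithmetic():
    from igtscan.search import DirectionSummary
    rows = [DirectionSummary("G. raimondii", "nu_to_mt", 38.74, 1),
            DirectionSummary("G. raimondii", "cp_to_mt", 12.89, 1),
            DirectionSummary("G. hirsutum", "cp_to_nu", 4275.84, 1),
            DirectionSummary("G. hirsutum", "mt_to_nu", 1092.08, 1)]
    assert direction_ratio(rows, "G. raimondii", "nu_to_mt", "cp_to_mt") == 3.01
    assert direction_ratio(rows, "G. hirsutum", "cp_to_nu", "mt_to_nu") == 3.92
    assert direction_ratio(rows, "G. raimondii", "nu_to_mt", "nu_to_mt") == 1.00
    assert math.isnan(direction_ratio(rows, "G. hirsutum", "cp_to_nu", "nu_to_cp"))


def test_nu_to_mt_species_mean():
    # four per-species totals; their mean to two decimals
    totals = [38.74, 41.94, 37.99, 40.50]
    assert round(sum(totals) / 4, 2) == 39.79


def test_percent_of_genome_published_arithmetic():
    assert percent_of_genome(1107, 761.57) == 0.15
    assert percent_of_genome(4276, 2173.00) == 0.20
    assert percent_of_genome(0, 100.0) == 0.00
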