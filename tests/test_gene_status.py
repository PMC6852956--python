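import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from igtscan.core_io import GenomeRecord, revcomp
from igtscan.gene_status import (GeneTransferState, assess_gene_in_organelle,
                                 assess_gene_in_recipient, build_state_matrix,
                                 call_gene_states, transferred_counts, translate)
from igtscan.panels import CP_PANEL, MT_PANEL, GenePanel, PanelGene
from igtscan.search import SearchParams, filter_hits, search
from igtscan.simulate import (plant_pseudogenizing_mutation, random_cds,
                              random_dna)


def test_translate_canonical_codons():
    assert translate("ATGTAA") == "M*"
    assert translate("ATGTGGTAA") == "MW*"


def test_translate_trailing_bases_ignored():
    assert translate("ATGTAAC") == "M*"


def test_translate_matches_codon_table_oracle():
    rng = np.random.default_rng(0)
    seq = random_dna(999, rng)
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    stops = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
    expected = "".join(
        "*" if seq[i:i + 3] in stops else fwd[seq[i:i + 3]]
        for i in range(0, 999, 3))
    assert translate(seq) == expected


def _planted_recipient(gene_seq, copy_seq, rng):
    flank = random_dna(3000, rng)
    flank2 = random_dna(3000, rng)
    rec = GenomeRecord("chr", "sp", "nuclear", flank + copy_seq + flank2)
    query = GenomeRecord("g", "sp", "nuclear", gene_seq)
    params = SearchParams()
    hits = filter_hits(search(query, rec, params), "norg", params)
    return rec, hits


def test_verbatim_full_length_copy_called_intact():
    rng = np.random.default_rng(1)
    gene = random_cds(150, rng)
    rec, hits = _planted_recipient(gene, gene, rng)
    st = assess_gene_in_recipient(PanelGene("g", "protein", "x"), gene, hits, rec,
                                  "sp", "mt_to_nu")
    assert st.state == "intact" and not st.premature_stop
    assert st.coverage >= 0.99


def test_stop_codon_copy_called_pseudogene():
    rng = np.random.default_rng(2)
    gene = random_cds(150, rng)
    broken = plant_pseudogenizing_mutation(gene, rng).sequence
    rec, hits = _planted_recipient(gene, broken, rng)
    st = assess_gene_in_recipient(PanelGene("g", "protein", "x"), gene, hits, rec,
                                  "sp", "mt_to_nu")
    assert st.state == "pseudogene" and st.premature_stop


def test_half_length_fragment_called_pseudogene():
    rng = np.random.default_rng(3)
    gene = random_cds(200, rng)
    rec, hits = _planted_recipient(gene, gene[: len(gene) // 2], rng)
    st = assess_gene_in_recipient(PanelGene("g", "protein", "x"), gene, hits, rec,
                                  "sp", "mt_to_nu")
    assert st.state == "pseudogene" and not st.premature_stop
    assert st.coverage < 0.99


def test_reverse_orientation_copy_still_intact():
    rng = np.random.default_rng(4)
    gene = random_cds(150, rng)
    rec, hits = _planted_recipient(gene, revcomp(gene), rng)
    st = assess_gene_in_recipient(PanelGene("g", "protein", "x"), gene, hits, rec,
                                  "sp", "mt_to_nu")
    assert st.state == "intact"


def test_no_hits_called_absent_and_absent_carries_no_hit():
    st = assess_gene_in_recipient(PanelGene("g", "protein", "x"), "ATG" + "AAA" * 60 + "TAA",
                                  [], GenomeRecord("chr", "sp", "nuclear", "ACGT" * 100),
                                  "sp", "mt_to_nu")
    assert st.state == "absent" and st.best_hit is None
    with pytest.raises(ValueError):
        GeneTransferState("g", "sp", "mt_to_nu", "nope")


def test_raising_coverage_threshold_never_promotes_to_intact():
    rng = np.random.default_rng(5)
    gene = random_cds(200, rng)
    for copy in (gene, gene[: int(len(gene) * 0.8) // 3 * 3]):
        rec, hits = _planted_recipient(gene, copy, rng)
        states = [assess_gene_in_recipient(PanelGene("g", "protein", "x"), gene, hits,
                                           rec, "sp", "mt_to_nu",
                                           intact_coverage_threshold=th).state
                  for th in (0.5, 0.8, 0.99)]
        for a, b in zip(states, states[1:]):
            assert not (a == "pseudogene" and b == "intact")


def test_organelle_presence_and_loss(sim):
    gs = sim.genome_set
    mt = gs.records_for("A2", "mitochondrial")[0]
    present_gene = next(g for g in MT_PANEL.genes if g.name == "nad1")
    lost_gene = next(g for g in MT_PANEL.genes if g.name == "rps1")
    assert assess_gene_in_organelle(present_gene, sim.mt_gene_refs["nad1"], mt) == "present"
    assert assess_gene_in_organelle(lost_gene, sim.mt_gene_refs["rps1"], mt) == \
        "lost_from_organelle"


def test_deleted_panel_genes_flagged_lost(sim):
    gs = sim.genome_set
    mt = gs.records_for("A2", "mitochondrial")[0]
    expected = set(sim.config.mt_gene_losses)
    subset = list(expected) + ["nad2", "cox1", "atp9"]
    lost = {n for n in subset
            if assess_gene_in_organelle(
                next(g for g in MT_PANEL.genes if g.name == n),
                sim.mt_gene_refs[n], mt) == "lost_from_organelle"}
    assert lost == expected


def test_build_state_matrix_counts_and_missing_cells():
    panel = GenePanel("p3", [PanelGene("a", "protein", "x"),
                             PanelGene("b", "protein", "x"),
                             PanelGene("c", "protein", "x")])
    states = [GeneTransferState(g, sp, "mt_to_nu", "absent")
              for g in "abc" for sp in ("s1", "s2")]
    mat = build_state_matrix(panel, ["s1", "s2"], states)
    assert transferred_counts(mat).tolist() == [0, 0]
    with pytest.raises(ValueError, match="missing state cells"):
        build_state_matrix(panel, ["s1", "s2"], states[:-1])
    with pytest.raises(ValueError, match="duplicate"):
        build_state_matrix(panel, ["s1", "s2"], states + [states[0]])


def test_detection_recovers_planted_gene_states(sim):
    """On zero-to-low divergence planted copies, called states match the
    simulated per-gene history exactly."""
    gs = sim.genome_set
    sp = "AD1"
    mt = gs.records_for(sp, "mitochondrial")[0]
    gene_seqs = {}
    for f in gs.features_for(mt.id, "gene"):
        s = mt.fetch(f.start, f.end)
        gene_seqs[f.name] = revcomp(s) if f.strand == "-" else s
    states = call_gene_states(MT_PANEL, gene_seqs, gs.records_for(sp, "nuclear"),
                              sp, "mt_to_nu")
    called = {st.gene: st.state for st in states}
    truth = sim.gene_state_truth["mt_to_nu"][sp]
    for g in MT_PANEL.gene_names:
        expected = truth.get(g, "absent")
        assert called[g] == expected, (g, expected, called[g])
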