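"""Per-gene transfer-state calls.

For each (gene, species, direction) the nuclear (or mitochondrial) copy of
an organellar gene is classified as:

* ``intact`` — merged hit coverage of the gene is at least the full-length
  threshold (default 0.99) and, for protein genes, the recipient copy
  translated in the donor's frame has no internal stop codon;
* ``pseudogene`` — a qualifying hit exists but the copy is not full length
  or carries a premature stop;
* ``absent`` — no qualifying hit.

The donor-side call ``lost_from_organelle`` marks genes missing from the
organelle genome itself; it is independent of recipient hits.  tRNA/rRNA
genes have no reading frame and are decided on coverage alone.  The frame
for the stop-codon check is inherited from the donor gene through the
alignment, not re-predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .core_io import GenomeRecord, revcomp
from .panels import GenePanel, PanelGene
from .search import SearchParams, TransferHit, filter_hits, merge_hits, search, union_length

STATES = ("intact", "pseudogene", "absent", "lost_from_organelle")
_TABLES = {"standard": 1, "bacterial": 11}


@dataclass
class GeneTransferState:
    gene: str
    species: str
    direction: str
    state: str
    best_hit: TransferHit | None = None
    coverage: float = 0.0
    premature_stop: bool = False

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "absent" and self.best_hit is not None:
            raise ValueError("absent state cannot carry a hit")


def translate(seq: str, table: str = "standard") -> str:
    """Codon-by-codon translation of the first reading frame; internal
    stops are emitted as '*'; trailing bases beyond a codon multiple are
    ignored."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(table=_TABLES[table]))


def gene_hit_coverage(gene_length: int, hits: list[TransferHit]) -> float:
    """Fraction of the gene (as query) covered by the union of its hits'
    donor intervals."""
    if not hits:
        return 0.0
    covered = union_length([(max(0, h.donor_start), min(gene_length, h.donor_end))
                            for h in hits])
    return covered / gene_length


def _recipient_copy_in_frame(gene_length: int, hit: TransferHit,
                             recipient: GenomeRecord) -> str:
    """Extract the recipient copy of the best hit and orient/frame it like
    the donor gene."""
    seg = recipient.fetch(hit.recipient_start, hit.recipient_end)
    if hit.orientation == "reverse":
        seg = revcomp(seg)
    offset = (3 - hit.donor_start % 3) % 3
    return seg[offset:]


def assess_gene_in_recipient(gene: PanelGene, gene_sequence: str,
                             hits: list[TransferHit], recipient: GenomeRecord,
                             species: str, direction: str,
                             intact_coverage_threshold: float = 0.99,
                             table: str = "standard") -> GeneTransferState:
    """Call intact/pseudogene/absent for one gene's copy in a recipient
    genome, given hits from a search with the gene as query."""
    if not gene_sequence:
        raise ValueError(f"gene {gene.name!r}: missing sequence")
    if not hits:
        return GeneTransferState(gene.name, species, direction, "absent")
    coverage = gene_hit_coverage(len(gene_sequence), hits)
    best = max(hits, key=lambda h: (h.score, -h.recipient_start))
    premature = False
    if gene.gene_type == "protein":
        copy = _recipient_copy_in_frame(len(gene_sequence), best, recipient)
        if len(copy) >= 3:
            aa = translate(copy, table)
            premature = "*" in aa[:-1]
    state = ("intact" if coverage >= intact_coverage_threshold and not premature
             else "pseudogene")
    return GeneTransferState(gene.name, species, direction, state,
                             best_hit=best, coverage=coverage,
                             premature_stop=premature)


def assess_gene_in_organelle(gene: PanelGene, reference_sequence: str,
                             organelle: GenomeRecord,
                             params: SearchParams | None = None,
                             intact_coverage_threshold: float = 0.99) -> str:
    """``present`` if the organelle genome carries the panel reference at
    full-length coverage, ``lost_from_organelle`` otherwise."""
    query = GenomeRecord(f"panel_{gene.name}", organelle.species,
                         organelle.compartment, reference_sequence)
    params = params or SearchParams(min_length=min(50, len(reference_sequence)))
    hits = [h for h in search(query, organelle, params)
            if h.identity >= params.min_identity]
    coverage = gene_hit_coverage(len(reference_sequence), hits)
    return "present" if coverage >= intact_coverage_threshold else "lost_from_organelle"


def call_gene_states(panel: GenePanel, gene_sequences: dict[str, str],
                     recipients: list[GenomeRecord], species: str, direction: str,
                     params: SearchParams | None = None,
                     intact_coverage_threshold: float = 0.99) -> list[GeneTransferState]:
    """Search every panel gene against the recipient sequences of one
    species and call its transfer state."""
    params = params or SearchParams()
    out = []
    for pg in panel.genes:
        seq = gene_sequences.get(pg.name)
        if seq is None:
            out.append(GeneTransferState(pg.name, species, direction, "absent"))
            continue
        query = GenomeRecord(pg.name, species, "nuclear", seq)
        gene_hits: list[tuple[GenomeRecord, TransferHit]] = []
        for rec in recipients:
            gp = params
            if len(seq) < params.min_length:
                gp = SearchParams(**{**params.__dict__, "min_length": max(params.k, len(seq) // 2)})
            for h in filter_hits(search(query, rec, gp), "norg", gp):
                gene_hits.append((rec, h))
        if not gene_hits:
            out.append(GeneTransferState(pg.name, species, direction, "absent"))
            continue
        best_rec = max(gene_hits, key=lambda rh: rh[1].score)[0]
        out.append(assess_gene_in_recipient(
            pg, seq, [h for _r, h in gene_hits], best_rec, species, direction,
            intact_coverage_threshold))
    return out


def build_state_matrix(panel: GenePanel, species_list: list[str],
                       states: list[GeneTransferState]) -> pd.DataFrame:
    """Genes x species matrix of transfer states.

    Every (gene, species) cell must be covered exactly once; transferred
    counts per species are #(intact) + #(pseudogene).
    """
    cells: dict[tuple[str, str], str] = {}
    for st in states:
        key = (st.gene, st.species)
        if key in cells:
            raise ValueError(f"duplicate state for gene={st.gene} species={st.species}")
        cells[key] = st.state
    missing = [(g, sp) for g in panel.gene_names for sp in species_list
               if (g, sp) not in cells]
    if missing:
        raise ValueError(f"missing state cells: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    data = {sp: [cells[(g, sp)] for g in panel.gene_names] for sp in species_list}
    return pd.DataFrame(data, index=panel.gene_names)


def transferred_counts(matrix: pd.DataFrame) -> pd.Series:
    """Per-species number of transferred genes (intact + pseudogene)."""
    return matrix.isin(["intact", "pseudogene"]).sum(axis=0)


def transferred_sets(matrix: pd.DataFrame) -> dict[str, set[str]]:
    return {sp: set(matrix.index[matrix[sp].isin(["intact", "pseudogene"])])
            for sp in matrix.columns}
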