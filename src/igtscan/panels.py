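"""Reference gene panels for the organellar compartments.

The mitochondrial panel holds the 42 protein-coding genes conserved across
seed-plant mitogenomes (NADH dehydrogenase, succinate dehydrogenase,
cytochrome pathway, ATP synthase, cytochrome c maturation, ribosomal
proteins, matR and mttB).  The plastid panel holds 78 chloroplast genes
covering both photosystems, the cytochrome b6f complex, ATP synthase, the
NDH complex, rubisco, the plastid-encoded polymerase, ribosomal proteins
and the conserved ORFs.  These are the gene universes over which
transfer-state matrices are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PanelGene:
    name: str
    gene_type: str  # "protein" | "tRNA" | "rRNA"
    category: str


@dataclass
class GenePanel:
    """A named, ordered collection of unique reference genes."""

    name: str
    genes: list[PanelGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names in panel {self.name!r}: {dupes}")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, name: str) -> bool:
        return any(g.name == name for g in self.genes)


def _panel(name: str, spec: list[tuple[str, str]]) -> GenePanel:
    return GenePanel(name, [PanelGene(g, "protein", cat) for g, cat in spec])


_MT_SPEC: list[tuple[str, str]] = (
    [(f"nad{x}", "complex I (NADH dehydrogenase)")
     for x in ["1", "2", "3", "4", "4L", "5", "6", "7", "9"]]
    + [(g, "ATP synthase") for g in ["atp1", "atp4", "atp6", "atp8", "atp9"]]
    + [(g, "complex IV (cytochrome c oxidase)") for g in ["cox1", "cox2", "cox3"]]
    + [("cob", "complex III (cytochrome b)")]
    + [(g, "cytochrome c biogenesis") for g in ["ccmB", "ccmC", "ccmFC", "ccmFN"]]
    + [("matR", "maturase"), ("mttB", "transport membrane protein")]
    + [(g, "complex II (succinate dehydrogenase)") for g in ["sdh3", "sdh4"]]
    + [(g, "ribosomal protein (large subunit)")
       for g in ["rpl2", "rpl5", "rpl6", "rpl10", "rpl16"]]
    + [(g, "ribosomal protein (small subunit)")
       for g in ["rps1", "rps2", "rps3", "rps4", "rps7", "rps10", "rps11",
                 "rps12", "rps13", "rps14", "rps19"]]
)

_CP_SPEC: list[tuple[str, str]] = (
    [(g, "photosystem I") for g in ["psaA", "psaB", "psaC", "psaI", "psaJ"]]
    + [(g, "photosystem II")
       for g in ["psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH",
                 "psbI", "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ"]]
    + [(g, "cytochrome b6f complex")
       for g in ["petA", "petB", "petD", "petG", "petL", "petN"]]
    + [(g, "ATP synthase")
       for g in ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"]]
    + [(f"ndh{x}", "NADH dehydrogenase")
       for x in ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K"]]
    + [("rbcL", "rubisco large subunit")]
    + [(g, "RNA polymerase") for g in ["rpoA", "rpoB", "rpoC1", "rpoC2"]]
    + [(g, "ribosomal protein (small subunit)")
       for g in ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12",
                 "rps14", "rps15", "rps16", "rps18", "rps19"]]
    + [(g, "ribosomal protein (large subunit)")
       for g in ["rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23",
                 "rpl32", "rpl33", "rpl36"]]
    + [("matK", "maturase"), ("clpP", "protease"), ("cemA", "envelope membrane protein"),
       ("ccsA", "cytochrome c synthesis"), ("accD", "acetyl-CoA carboxylase")]
    + [(f"ycf{x}", "conserved ORF") for x in ["1", "2", "3", "4"]]
)

#: 42 mitochondrial protein-coding genes (the standard seed-plant panel).
MT_PANEL = _panel("mt42", _MT_SPEC)

#: 78 chloroplast genes.
CP_PANEL = _panel("cp78", _CP_SPEC)

#: Ribosomal-protein genes absent from the mitogenome of every simulated
#: species by default (shared ancestral loss).
DEFAULT_MT_LOSSES = ("rpl6", "rps1", "rps2", "rps11", "rps13", "rps19")

assert len(MT_PANEL) == 42
assert len(CP_PANEL) == 78
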