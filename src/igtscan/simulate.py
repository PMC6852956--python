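"""Synthetic genome sets with planted intergenomic transfers.

The generator emulates a four-species allopolyploid study system: two
diploids (A2, D5) and two allotetraploids (AD1, AD2) derived from a single
hybridization of the two diploid lineages.  All four species share one
ancestral mitogenome and plastome (organelle genomes are highly conserved
at this timescale); nuclear chromosomes are independent random backgrounds
per species into which transfers are spliced with known ground truth:

* organelle-to-nucleus insertions (numts/nupts), both gene-anchored copies
  whose presence/decay pattern is simulated over the species network, and
  background segments of controlled length, age (per-site divergence),
  orientation and junction microhomology;
* chloroplast insertions into the mitogenome (mtpts), anchored on eight
  tRNA-like plastid genes and planted ancestrally so their junctions are
  shared by all species;
* nuclear segments and a labelled repeat library planted (diverged) into
  the mitogenome;
* 125-nt paired reads with per-copy expression levels.

Decay is substitution-only by default so identity/coverage arithmetic is
exact; the background is i.i.d. uniform DNA, so chance 100-bp 95%-identity
matches are essentially impossible and detection false positives can be
attributed.  Everything is deterministic given the seed: one global seed is
forked into independent streams by stable string labels, so changing one
planting count does not perturb unrelated draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureRecord, GenomeRecord, GenomeSet, revcomp
from .panels import CP_PANEL, DEFAULT_MT_LOSSES, MT_PANEL
from .polyploid import SpeciesNetwork, cotton_network

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_TRN_NAMES = ("trnD", "trnH", "trnM", "trnN", "trnP", "trnS", "trnV", "trnW")
REPEAT_CLASSES = ("copia", "gypsy", "LTR_retro_unclassified", "TE",
                  "simple_repeat", "low_complexity", "unspecified")


class SimulationError(ValueError):
    pass


def _rng(seed: int, *labels) -> np.random.Generator:
    """Independent stream derived from the run seed and stable labels."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(entropy)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode()


def mutate_sequence(seq: str, age: float, rng: np.random.Generator | int) -> str:
    """Substitute each site independently with probability ``age`` to a
    uniformly chosen different base; length is preserved.  ``age`` is the
    per-site divergence of the decayed copy from its source."""
    if not (0.0 <= age <= 0.5):
        raise ValueError("age must be in [0, 0.5]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if age == 0.0 or not seq:
        return seq
    from .search import encode
    arr = encode(seq).copy()
    sites = np.flatnonzero((rng.random(len(arr)) < age) & (arr != 4))
    if len(sites):
        arr[sites] = (arr[sites] + rng.integers(1, 4, len(sites))) % 4
    out = _DNA[np.where(arr == 4, 0, arr)].tobytes().decode()
    # restore Ns untouched
    if "N" in seq:
        out = "".join(o if s != "N" else "N" for o, s in zip(out, seq))
    return out


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop internal codons + TAA."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases
              if a + b + c not in _STOPS]
    body = rng.choice(len(codons), n_codons - 2)
    return "ATG" + "".join(codons[i] for i in body) + "TAA"


def _mutate_cds_keep_frame(seq: str, age: float, rng: np.random.Generator,
                           max_tries: int = 60) -> str:
    """Mutate a coding sequence while keeping it stop-free internally
    (resamples until the decayed copy still translates cleanly)."""
    from .gene_status import translate
    for _ in range(max_tries):
        out = mutate_sequence(seq, age, rng)
        if "*" not in translate(out)[:-1]:
            return out
    raise SimulationError("could not mutate CDS without creating a stop codon")


@dataclass
class PseudogenizedCopy:
    sequence: str
    n_substitutions: int
    flagged: bool  # True when a 2-substitution edit was required


def plant_pseudogenizing_mutation(gene_seq: str,
                                  rng: np.random.Generator | int) -> PseudogenizedCopy:
    """Introduce one internal in-frame premature stop codon (1 substitution
    where possible, otherwise 2, flagged)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(gene_seq)
    if n < 6 or n % 3 != 0:
        raise ValueError("gene length must be >= 6 and a multiple of 3")
    candidates: list[tuple[int, str, int]] = []  # (codon index, stop, distance)
    n_codons = n // 3
    for ci in range(1, n_codons - 1):
        codon = gene_seq[3 * ci : 3 * ci + 3]
        for stop in _STOPS:
            dist = sum(a != b for a, b in zip(codon, stop))
            if 1 <= dist <= 2:
                candidates.append((ci, stop, dist))
    if not candidates:
        raise SimulationError("no internal codon mutable to a stop in <=2 substitutions")
    best = min(c[2] for c in candidates)
    pool = [c for c in candidates if c[2] == best]
    ci, stop, dist = pool[rng.integers(0, len(pool))]
    out = gene_seq[: 3 * ci] + stop + gene_seq[3 * ci + 3 :]
    return PseudogenizedCopy(out, dist, flagged=dist > 1)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class DirectionTransferSpec:
    """Planted background (non-gene) transfers for one direction."""

    n_background: int = 0
    length_min: int = 200
    length_max: int = 2000
    divergence: float = 0.01
    reverse_prob: float = 0.5
    microhomology_length: int = 4
    hotspot_weight: float = 0.0  # fraction of sources drawn from the donor hotspot

    def __post_init__(self) -> None:
        for p in (self.divergence, self.reverse_prob, self.hotspot_weight):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.length_min < 1:
            raise ValueError("transfer lengths must be >= 1")


@dataclass
class GeneTransferSpec:
    """Network-simulated gene-anchored transfer history for one direction."""

    gain_root_prob: float = 0.5
    gain_edge_prob: float = 0.1
    loss_prob_polyploid: float = 0.35
    loss_prob_diploid: float = 0.05
    decay_prob_polyploid: float = 0.2
    decay_prob_diploid: float = 0.05
    divergence: float = 0.005
    microhomology_length: int = 4
    truncate_fraction: tuple[float, float] = (0.4, 0.7)


@dataclass
class RepeatSpec:
    classes: tuple[str, ...] = REPEAT_CLASSES
    elements_per_class: int = 2
    copies_per_element: int = 1
    length_min: int = 300
    length_max: int = 1500
    divergence: float = 0.05


@dataclass
class ReadSpec:
    read_length: int = 125
    error_rate: float = 0.002
    fragment_min: int = 200
    fragment_max: int = 300


@dataclass
class SimulationConfig:
    seed: int = 0
    network: SpeciesNetwork | None = None  # default: the two-diploid + allopolyploid network
    n_nuclear_chromosomes: int = 2
    nuclear_background_length: int = 150_000
    mito_background_length: int = 250_000
    lsc_background_length: int = 40_000
    ssc_background_length: int = 12_000
    ir_length: int = 25_000
    gene_codons_min: int = 100
    gene_codons_max: int = 400
    trn_gene_length: int = 72
    mt_gene_losses: tuple[str, ...] = DEFAULT_MT_LOSSES
    transfers: dict[str, DirectionTransferSpec] = field(default_factory=lambda: {
        "mt_to_nu": DirectionTransferSpec(n_background=30, hotspot_weight=0.3),
        "cp_to_nu": DirectionTransferSpec(n_background=50),
        "cp_to_mt": DirectionTransferSpec(n_background=2, divergence=0.02),
        "nu_to_mt": DirectionTransferSpec(n_background=10, divergence=0.03),
    })
    gene_transfers: dict[str, GeneTransferSpec] = field(default_factory=lambda: {
        "mt_to_nu": GeneTransferSpec(gain_root_prob=0.5, gain_edge_prob=0.12,
                                     loss_prob_polyploid=0.45, loss_prob_diploid=0.05,
                                     decay_prob_polyploid=0.25, decay_prob_diploid=0.05),
        "cp_to_nu": GeneTransferSpec(gain_root_prob=0.85, gain_edge_prob=0.1,
                                     loss_prob_polyploid=0.03, loss_prob_diploid=0.08,
                                     decay_prob_polyploid=0.08, decay_prob_diploid=0.1),
    })
    mtpt_divergence: float = 0.01
    mtpt_microhomology: int = 4
    repeats: RepeatSpec = field(default_factory=RepeatSpec)
    reads: ReadSpec = field(default_factory=ReadSpec)
    indel_rate: float = 0.0  # substitution-only decay is the supported mode

    def __post_init__(self) -> None:
        if self.network is None:
            self.network = cotton_network()
        if self.indel_rate != 0.0:
            raise NotImplementedError(
                "small-indel decay is not supported by the ungapped engine")

    @property
    def species(self) -> list[str]:
        return list(self.network.leaves)


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion."""

    insertion_id: str
    species: str
    direction: str
    donor_seq: str
    donor_start: int
    donor_end: int
    recipient_seq: str
    recipient_start: int
    recipient_end: int
    orientation: str
    planted_divergence: float
    microhomology_length: int
    pseudogenized: bool = False
    gene_name: str | None = None

    @property
    def recipient_interval(self) -> tuple[int, int]:
        return (self.recipient_start, self.recipient_end)


@dataclass
class SimulationResult:
    genome_set: GenomeSet
    truth: list[TruthRecord]
    gene_state_truth: dict[str, pd.DataFrame]  # direction -> genes x species states
    repeat_library: list[tuple[str, str, str]]  # (element name, class, sequence)
    repeat_class_truth: dict[str, int]          # class -> planted bp in the mitogenome
    mt_hotspot: tuple[int, int]
    plastome_partition: "object"
    network: SpeciesNetwork
    config: SimulationConfig
    mt_gene_refs: dict[str, str] = field(default_factory=dict)   # ancestral CDS
    cp_gene_refs: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        # allows: genome_set, truth = simulate_genome_set(cfg)
        return iter((self.genome_set, self.truth))


# ---------------------------------------------------------------------------
# construction helpers

@dataclass
class _Insert:
    pos: int          # position on the background sequence
    seq: str
    up: str = ""      # overwrites background [pos-len(up), pos)
    down: str = ""    # overwrites background [pos, pos+len(down))
    tag: object = None


def _splice(background: str, inserts: list[_Insert]) -> tuple[str, list[tuple[int, int, object]]]:
    """Splice inserts into a background, overwriting the flank windows with
    the provided up/down strings.  Returns the final sequence and the final
    coordinates of each insert's core sequence."""
    inserts = sorted(inserts, key=lambda i: i.pos)
    parts: list[str] = []
    coords: list[tuple[int, int, object]] = []
    cursor = 0
    out_len = 0
    for ins in inserts:
        a, b = ins.pos - len(ins.up), ins.pos + len(ins.down)
        if a < cursor or b > len(background):
            raise SimulationError("insert positions overlap or exceed the background")
        parts.append(background[cursor:a])
        out_len += a - cursor
        parts.append(ins.up)
        out_len += len(ins.up)
        coords.append((out_len, out_len + len(ins.seq), ins.tag))
        parts.append(ins.seq)
        out_len += len(ins.seq)
        parts.append(ins.down)
        out_len += len(ins.down)
        cursor = b
    parts.append(background[cursor:])
    return "".join(parts), coords


def _spaced_positions(rng: np.random.Generator, n: int, low: int, high: int,
                      min_gap: int) -> np.ndarray:
    """n sorted positions in [low, high) pairwise separated by >= min_gap."""
    span = (high - low) - (n - 1) * min_gap
    if n == 0:
        return np.empty(0, dtype=int)
    if span <= n:
        raise SimulationError(
            f"cannot place {n} insertions with spacing {min_gap} in [{low},{high})")
    xs = np.sort(rng.random(n) * span)
    return (low + xs + np.arange(n) * min_gap).astype(int)


def _sample_source(rng: np.random.Generator, genome_len: int, length: int,
                   forbidden: list[tuple[int, int]], margin: int = 20,
                   window: tuple[int, int] | None = None,
                   max_tries: int = 2000) -> tuple[int, int]:
    """A donor interval of the given length avoiding forbidden intervals
    (with a flank margin); optionally restricted to a window."""
    lo, hi = (window or (0, genome_len))
    if hi - lo < length + 2 * margin:
        raise SimulationError("source window too small")
    for _ in range(max_tries):
        s = int(rng.integers(lo + margin, hi - length - margin + 1))
        e = s + length
        if all(e + margin <= fs or s - margin >= fe for fs, fe in forbidden):
            return s, e
    raise SimulationError("could not sample a source interval avoiding planted regions")


def _transfer_insert(donor: GenomeRecord, src: tuple[int, int], divergence: float,
                     reverse: bool, mh: int, rng: np.random.Generator,
                     pos: int, tag: object) -> _Insert:
    s, e = src
    ins_seq = mutate_sequence(donor.fetch(s, e), divergence, rng)
    up = donor.fetch(s - mh, s) if mh else ""
    down = donor.fetch(e, e + mh) if mh else ""
    if reverse:
        ins_seq = revcomp(ins_seq)
        up, down = revcomp(down), revcomp(up)
    return _Insert(pos=pos, seq=ins_seq, up=up, down=down, tag=tag)


# ---------------------------------------------------------------------------
# gene-history simulation over the species network

def _simulate_gene_states(genes: Sequence[str], net: SpeciesNetwork,
                          spec: GeneTransferSpec,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene presence/decay states at the leaves under a single-gain
    history with node-wise loss and decay probabilities."""
    poly = net.polyploid_nodes()
    rows = {}
    topo = net.topological_nodes()
    for gene in genes:
        gained_at = None
        if rng.random() < spec.gain_root_prob:
            gained_at = net.root
        else:
            for node in topo[1:]:
                if rng.random() < spec.gain_edge_prob:
                    gained_at = node
                    break
        state: dict[str, str] = {}
        for node in topo:
            if gained_at is None:
                state[node] = "absent"
                continue
            if node == gained_at:
                state[node] = "intact"
                continue
            parents = net.parents(node)
            if not parents:
                state[node] = "absent"
                continue
            parent_states = [state[p] for p in parents]
            if all(s == "absent" for s in parent_states):
                state[node] = "absent"
                continue
            loss_p = spec.loss_prob_polyploid if node in poly else spec.loss_prob_diploid
            if rng.random() < loss_p:
                state[node] = "absent"
                continue
            inherited = "pseudogene" if all(
                s == "pseudogene" for s in parent_states if s != "absent") else "intact"
            if inherited == "intact":
                decay_p = (spec.decay_prob_polyploid if node in poly
                           else spec.decay_prob_diploid)
                if rng.random() < decay_p:
                    inherited = "pseudogene"
            state[node] = inherited
        rows[gene] = {leaf: state[leaf] for leaf in net.leaves}
    return pd.DataFrame.from_dict(rows, orient="index")[list(net.leaves)]


# ---------------------------------------------------------------------------
# the generator

def simulate_genome_set(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate the full four-species, three-compartment genome set with
    planted transfers and ground truth.  Deterministic given the seed."""
    from .hotspots import PlastomePartition

    cfg = config or SimulationConfig()
    seed = cfg.seed
    net = cfg.network
    species = cfg.species
    truth: list[TruthRecord] = []
    records: list[GenomeRecord] = []
    features: list[FeatureRecord] = []

    # --- shared gene repertoires -------------------------------------------
    g = _rng(seed, "mt_genes")
    mt_gene_seqs = {pg.name: random_cds(int(g.integers(cfg.gene_codons_min,
                                                       cfg.gene_codons_max + 1)), g)
                    for pg in MT_PANEL.genes}
    g = _rng(seed, "cp_genes")
    cp_gene_seqs = {pg.name: random_cds(int(g.integers(cfg.gene_codons_min,
                                                       cfg.gene_codons_max + 1)), g)
                    for pg in CP_PANEL.genes}
    trn_seqs = {name: random_dna(cfg.trn_gene_length, g) for name in _TRN_NAMES}

    # --- plastome (shared, circular, quadripartite) ------------------------
    p = _rng(seed, "plastome")
    lsc_gene_names = CP_PANEL.gene_names[:57]
    ssc_gene_names = CP_PANEL.gene_names[57:]
    lsc_inserts = [(name, cp_gene_seqs[name], "gene") for name in lsc_gene_names]
    lsc_inserts += [(name, trn_seqs[name], "tRNA") for name in _TRN_NAMES]

    def _region(bg_len: int, gene_items, rng_):
        bg = random_dna(bg_len, rng_)
        pos = _spaced_positions(rng_, len(gene_items), 60, bg_len - 60,
                                max(120, (bg_len - 200) // max(1, len(gene_items)) // 2))
        inserts = [_Insert(pos=int(pp), seq=seq, tag=(name, ftype))
                   for pp, (name, seq, ftype) in zip(pos, gene_items)]
        return _splice(bg, inserts)

    lsc_seq, lsc_coords = _region(cfg.lsc_background_length, lsc_inserts, p)
    ssc_items = [(name, cp_gene_seqs[name], "gene") for name in ssc_gene_names]
    ssc_seq, ssc_coords = _region(cfg.ssc_background_length, ssc_items, p)
    ira = random_dna(cfg.ir_length, p)
    plastome_seq = lsc_seq + ira + ssc_seq + revcomp(ira)
    L_lsc, L_ir, L_ssc = len(lsc_seq), len(ira), len(ssc_seq)
    partition = PlastomePartition(
        lsc=(0, L_lsc), ira=(L_lsc, L_lsc + L_ir),
        ssc=(L_lsc + L_ir, L_lsc + L_ir + L_ssc),
        irb=(L_lsc + L_ir + L_ssc, len(plastome_seq)))
    cp_gene_feats: list[tuple[str, int, int, str]] = []
    for s, e, (name, ftype) in lsc_coords:
        cp_gene_feats.append((name, s, e, ftype))
    for s, e, (name, ftype) in ssc_coords:
        cp_gene_feats.append((name, s + L_lsc + L_ir, e + L_lsc + L_ir, ftype))

    # --- mitogenome (shared, circular) -------------------------------------
    m = _rng(seed, "mt_layout")
    mt_bg = random_dna(cfg.mito_background_length, m)
    placed_mt_genes = [n for n in MT_PANEL.gene_names if n not in cfg.mt_gene_losses]
    # the eight ancestral plastid tRNA insertions (mtpts)
    mtpt_items = list(_TRN_NAMES)
    # ancestral nuclear segments later planted verbatim in every nucleus
    pool_rng = _rng(seed, "nu_pool")
    nu_spec = cfg.transfers.get("nu_to_mt", DirectionTransferSpec(n_background=0))
    nu_pool = [random_dna(int(pool_rng.integers(nu_spec.length_min, nu_spec.length_max + 1)),
                          pool_rng)
               for _ in range(nu_spec.n_background)]
    rep = cfg.repeats
    rep_rng = _rng(seed, "repeats")
    repeat_library: list[tuple[str, str, str]] = []
    for cls in rep.classes:
        for j in range(rep.elements_per_class):
            length = int(rep_rng.integers(rep.length_min, rep.length_max + 1))
            repeat_library.append((f"{cls}#{j}", cls, random_dna(length, rep_rng)))
    cpmt_spec = cfg.transfers.get("cp_to_mt", DirectionTransferSpec(n_background=0))

    n_mt_inserts = (len(placed_mt_genes) + len(mtpt_items) + cpmt_spec.n_background
                    + len(nu_pool) + len(repeat_library) * rep.copies_per_element)
    mt_positions = _spaced_positions(
        m, n_mt_inserts, 200, cfg.mito_background_length - 200,
        max(600, (cfg.mito_background_length - 400) // max(1, n_mt_inserts) // 2))
    m.shuffle(mt_positions)
    mt_positions = list(int(x) for x in mt_positions)

    cp_record_proto = GenomeRecord("proto_cp", species[0], "chloroplast",
                                   plastome_seq, circular=True)
    cp_feat_by_name = {name: (s, e) for name, s, e, _ in cp_gene_feats}

    mt_inserts: list[_Insert] = []
    pi = 0
    for name in placed_mt_genes:
        strand = "+" if m.random() < 0.5 else "-"
        seq = mt_gene_seqs[name] if strand == "+" else revcomp(mt_gene_seqs[name])
        mt_inserts.append(_Insert(pos=mt_positions[pi], seq=seq,
                                  tag=("gene", name, strand)))
        pi += 1
    mtpt_rng = _rng(seed, "mtpt")
    for name in mtpt_items:
        s, e = cp_feat_by_name[name]
        reverse = bool(mtpt_rng.random() < 0.5)
        ins = _transfer_insert(cp_record_proto, (s, e), cfg.mtpt_divergence, reverse,
                               cfg.mtpt_microhomology, mtpt_rng, mt_positions[pi],
                               ("mtpt", name, (s, e), reverse))
        mt_inserts.append(ins)
        pi += 1
    for j in range(cpmt_spec.n_background):
        length = int(mtpt_rng.integers(cpmt_spec.length_min, cpmt_spec.length_max + 1))
        src = _sample_source(mtpt_rng, len(plastome_seq), length,
                             [(s, e) for _, s, e, _ in cp_gene_feats])
        reverse = bool(mtpt_rng.random() < cpmt_spec.reverse_prob)
        ins = _transfer_insert(cp_record_proto, src, cpmt_spec.divergence, reverse,
                               cpmt_spec.microhomology_length, mtpt_rng,
                               mt_positions[pi], ("cp_to_mt_bg", j, src, reverse))
        mt_inserts.append(ins)
        pi += 1
    for j, seg in enumerate(nu_pool):
        mt_inserts.append(_Insert(pos=mt_positions[pi],
                                  seq=mutate_sequence(seg, nu_spec.divergence, pool_rng),
                                  tag=("nu_to_mt", j)))
        pi += 1
    for name, cls, seq in repeat_library:
        for c in range(rep.copies_per_element):
            mt_inserts.append(_Insert(pos=mt_positions[pi],
                                      seq=mutate_sequence(seq, rep.divergence, rep_rng),
                                      tag=("repeat", name, cls)))
            pi += 1

    mt_seq, mt_coords = _splice(mt_bg, mt_inserts)
    mt_gene_feats: dict[str, tuple[int, int, str]] = {}
    mt_foreign: list[tuple[int, int]] = []
    mtpt_truth_proto = []   # (name, src interval, final mt interval, reverse)
    cpmt_bg_truth_proto = []
    nu_pool_mt: dict[int, tuple[int, int]] = {}
    repeat_annotations: list[tuple[int, int, str, str]] = []
    for s, e, tag in mt_coords:
        kind = tag[0]
        if kind == "gene":
            mt_gene_feats[tag[1]] = (s, e, tag[2])
        elif kind == "mtpt":
            mtpt_truth_proto.append((tag[1], tag[2], (s, e), tag[3]))
            mt_foreign.append((s, e))
        elif kind == "cp_to_mt_bg":
            cpmt_bg_truth_proto.append((tag[1], tag[2], (s, e), tag[3]))
            mt_foreign.append((s, e))
        elif kind == "nu_to_mt":
            nu_pool_mt[tag[1]] = (s, e)
            mt_foreign.append((s, e))
        elif kind == "repeat":
            repeat_annotations.append((s, e, tag[1], tag[2]))
            mt_foreign.append((s, e))
    repeat_class_truth = {cls: 0 for cls in rep.classes}
    for s, e, _name, cls in repeat_annotations:
        repeat_class_truth[cls] += e - s

    # donor hotspot: the largest annotation-free window of the mitogenome
    blocked = sorted(mt_foreign + [(s, e) for s, e, _ in mt_gene_feats.values()])
    gaps, prev = [], 0
    for s, e in blocked:
        gaps.append((prev, s))
        prev = e
    gaps.append((prev, len(mt_seq)))
    gs, ge = max(gaps, key=lambda iv: iv[1] - iv[0])
    mid = (gs + ge) // 2
    half = min(5000, (ge - gs) // 2 - 50)
    mt_hotspot = (mid - half, mid + half)

    # --- gene-anchored nuclear transfer histories --------------------------
    gene_state_truth: dict[str, pd.DataFrame] = {}
    _gene_pools = {"mt_to_nu": placed_mt_genes, "cp_to_nu": CP_PANEL.gene_names}
    for direction, pool in _gene_pools.items():
        if direction in cfg.gene_transfers:
            gene_state_truth[direction] = _simulate_gene_states(
                pool, net, cfg.gene_transfers[direction],
                _rng(seed, "states", direction))

    # --- per-species genomes ------------------------------------------------
    mt_genes_sorted = sorted(mt_gene_feats.items(), key=lambda kv: kv[1][0])
    for sp in species:
        mt_id, cp_id = f"{sp}_mt", f"{sp}_cp"
        records.append(GenomeRecord(mt_id, sp, "mitochondrial", mt_seq, circular=True))
        records.append(GenomeRecord(cp_id, sp, "chloroplast", plastome_seq, circular=True))
        for name, (s, e, strand) in mt_genes_sorted:
            features.append(FeatureRecord(mt_id, s, e, strand, "gene", name))
        for name, s, e, ftype in cp_gene_feats:
            features.append(FeatureRecord(cp_id, s, e, "+", ftype, name))
        for s, e, name, cls in repeat_annotations:
            features.append(FeatureRecord(mt_id, s, e, "+", "repeat", name,
                                          {"repeat_class": cls}))
        for name, src, (s, e), reverse in mtpt_truth_proto:
            truth.append(TruthRecord(
                f"{sp}:cp_to_mt:{name}", sp, "cp_to_mt", cp_id, src[0], src[1],
                mt_id, s, e, "reverse" if reverse else "positive",
                cfg.mtpt_divergence, cfg.mtpt_microhomology, gene_name=name))
        for j, src, (s, e), reverse in cpmt_bg_truth_proto:
            truth.append(TruthRecord(
                f"{sp}:cp_to_mt:bg{j}", sp, "cp_to_mt", cp_id, src[0], src[1],
                mt_id, s, e, "reverse" if reverse else "positive",
                cpmt_spec.divergence, cpmt_spec.microhomology_length))

    mt_record = records[0]          # shared sequence; per-species ids differ
    mt_gene_interval = {n: (s, e) for n, (s, e, _st) in mt_gene_feats.items()}
    mt_sources_forbidden = blocked  # genes + planted foreign segments
    cp_sources_forbidden = sorted((s, e) for _n, s, e, _t in cp_gene_feats)

    for sp in species:
        sp_rng = _rng(seed, "nucleus", sp)
        mt_id, cp_id = f"{sp}_mt", f"{sp}_cp"
        mt_rec = GenomeRecord(mt_id, sp, "mitochondrial", mt_seq, circular=True)
        cp_rec = GenomeRecord(cp_id, sp, "chloroplast", plastome_seq, circular=True)

        # assemble the list of planned nuclear inserts
        planned: list[tuple[str, object]] = []   # (kind, payload)
        mtnu = cfg.transfers.get("mt_to_nu", DirectionTransferSpec(n_background=0))
        cpnu = cfg.transfers.get("cp_to_nu", DirectionTransferSpec(n_background=0))
        for j in range(mtnu.n_background):
            planned.append(("bg", ("mt_to_nu", j)))
        for j in range(cpnu.n_background):
            planned.append(("bg", ("cp_to_nu", j)))
        for j in range(len(nu_pool)):
            planned.append(("pool", j))
        for direction, states in gene_state_truth.items():
            for gene in states.index:
                if states.loc[gene, sp] != "absent":
                    planned.append(("gene", (direction, gene, states.loc[gene, sp])))
        order = sp_rng.permutation(len(planned))
        planned = [planned[i] for i in order]

        n_chrom = cfg.n_nuclear_chromosomes
        per_chrom: list[list] = [[] for _ in range(n_chrom)]
        for item in planned:
            per_chrom[int(sp_rng.integers(0, n_chrom))].append(item)

        for ci in range(n_chrom):
            chrom_id = f"{sp}_chr{ci + 1}"
            bg = random_dna(cfg.nuclear_background_length, sp_rng)
            items = per_chrom[ci]
            positions = _spaced_positions(sp_rng, len(items), 300,
                                          cfg.nuclear_background_length - 300, 1200)
            inserts: list[_Insert] = []
            metas: list[tuple] = []
            for pos, (kind, payload) in zip(positions, items):
                pos = int(pos)
                if kind == "pool":
                    j = payload
                    inserts.append(_Insert(pos=pos, seq=nu_pool[j], tag=("pool", j)))
                    metas.append(("pool", j))
                elif kind == "bg":
                    direction, j = payload
                    spec = mtnu if direction == "mt_to_nu" else cpnu
                    donor = mt_rec if direction == "mt_to_nu" else cp_rec
                    forbidden = (mt_sources_forbidden if direction == "mt_to_nu"
                                 else cp_sources_forbidden)
                    length = int(sp_rng.integers(spec.length_min, spec.length_max + 1))
                    window = None
                    if spec.hotspot_weight and sp_rng.random() < spec.hotspot_weight:
                        window = mt_hotspot
                    # mt sources stay clear of planted mitogenome inserts by
                    # more than the cluster gap, so backwards homology through
                    # them cannot merge with genuine nu->mt insertions
                    margin = 600 if direction == "mt_to_nu" else 20
                    src = _sample_source(sp_rng, len(donor), length, forbidden,
                                         margin=margin, window=window)
                    reverse = bool(sp_rng.random() < spec.reverse_prob)
                    inserts.append(_transfer_insert(
                        donor, src, spec.divergence, reverse,
                        spec.microhomology_length, sp_rng, pos,
                        ("bg", direction, j, src, reverse, spec)))
                else:  # gene-anchored copy
                    direction, gene, state = payload
                    spec = cfg.gene_transfers[direction]
                    if direction == "mt_to_nu":
                        donor, src = mt_rec, mt_gene_interval[gene]
                    else:
                        donor, src = cp_rec, cp_feat_by_name[gene]
                    gene_seq = donor.fetch(*src)
                    strand = (mt_gene_feats[gene][2] if direction == "mt_to_nu" else "+")
                    cds = revcomp(gene_seq) if strand == "-" else gene_seq
                    mutated = _mutate_cds_keep_frame(cds, spec.divergence, sp_rng)
                    pseudo = state == "pseudogene"
                    if pseudo:
                        if sp_rng.random() < 0.5:
                            mutated = plant_pseudogenizing_mutation(mutated, sp_rng).sequence
                        else:
                            lo, hi = spec.truncate_fraction
                            frac = lo + (hi - lo) * sp_rng.random()
                            keep = 3 * max(2, int(len(mutated) * frac / 3))
                            mutated = mutated[:keep]
                    ins_seq = revcomp(mutated) if strand == "-" else mutated
                    reverse = bool(sp_rng.random() < 0.5)
                    mh = spec.microhomology_length
                    up = donor.fetch(src[0] - mh, src[0]) if mh else ""
                    down = donor.fetch(src[1], src[1] + mh) if mh else ""
                    if reverse:
                        ins_seq = revcomp(ins_seq)
                        up, down = revcomp(down), revcomp(up)
                    inserts.append(_Insert(pos=pos, seq=ins_seq, up=up, down=down,
                                           tag=("gene", direction, gene, src, reverse,
                                                pseudo, spec)))
            chrom_seq, coords = _splice(bg, inserts)
            records.append(GenomeRecord(chrom_id, sp, "nuclear", chrom_seq))
            for s, e, tag in coords:
                kind = tag[0]
                if kind == "pool":
                    j = tag[1]
                    features.append(FeatureRecord(chrom_id, s, e, "+", "region",
                                                  f"nu_source_{j}",
                                                  {"role": "nu_to_mt_source"}))
                    ms, me = nu_pool_mt[j]
                    truth.append(TruthRecord(
                        f"{sp}:nu_to_mt:{j}", sp, "nu_to_mt", chrom_id, s, e,
                        mt_id, ms, me, "positive", nu_spec.divergence, 0))
                elif kind == "bg":
                    _, direction, j, src, reverse, spec = tag
                    donor_id = mt_id if direction == "mt_to_nu" else cp_id
                    rec_id = f"{sp}:{direction}:bg{j}"
                    truth.append(TruthRecord(
                        rec_id, sp, direction, donor_id, src[0], src[1],
                        chrom_id, s, e, "reverse" if reverse else "positive",
                        spec.divergence, spec.microhomology_length))
                    features.append(FeatureRecord(chrom_id, s, e, "+", "insertion",
                                                  rec_id, {"direction": direction}))
                else:
                    _, direction, gene, src, reverse, pseudo, spec = tag
                    donor_id = mt_id if direction == "mt_to_nu" else cp_id
                    rec_id = f"{sp}:{direction}:{gene}"
                    truth.append(TruthRecord(
                        rec_id, sp, direction, donor_id, src[0], src[1],
                        chrom_id, s, e, "reverse" if reverse else "positive",
                        spec.divergence, spec.microhomology_length,
                        pseudogenized=pseudo, gene_name=gene))
                    features.append(FeatureRecord(chrom_id, s, e, "+", "insertion",
                                                  rec_id,
                                                  {"direction": direction, "gene": gene}))

    genome_set = GenomeSet(records=records, features=features,
                           species_list=list(species))
    return SimulationResult(
        genome_set=genome_set, truth=truth, gene_state_truth=gene_state_truth,
        repeat_library=repeat_library, repeat_class_truth=repeat_class_truth,
        mt_hotspot=mt_hotspot, plastome_partition=partition, network=net, config=cfg,
        mt_gene_refs=dict(mt_gene_seqs),
        cp_gene_refs={**cp_gene_seqs, **trn_seqs})


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimulatedReads:
    """Paired 125-nt reads with per-copy source truth."""

    pairs: list[tuple[tuple[str, str], tuple[str, str]]]  # ((name1, seq1), (name2, seq2))
    source_counts: dict[str, int]
    truncated: bool  # True when some copy was shorter than the read length

    @property
    def reads(self) -> list[tuple[str, str]]:
        out = []
        for r1, r2 in self.pairs:
            out.extend([r1, r2])
        return out


def simulate_reads(copies: Sequence[tuple[str, str]], levels: Sequence[float],
                   n_pairs: int, read_spec: ReadSpec | None = None,
                   rng: np.random.Generator | int = 0) -> SimulatedReads:
    """Simulate paired-end reads from a set of transcript copies.

    Pair counts are multinomial with probabilities proportional to
    level x copy length; fragment starts are uniform; each base is
    substituted with the per-base error rate.  The source copy is recorded
    in the read name.
    """
    spec = read_spec or ReadSpec()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if any(l < 0 for l in levels):
        raise ValueError("expression levels must be >= 0")
    weights = np.array([lvl * len(seq) for (_n, seq), lvl in zip(copies, levels)],
                       dtype=float)
    if weights.sum() == 0:
        return SimulatedReads([], {name: 0 for name, _ in copies}, False)
    counts = rng.multinomial(n_pairs, weights / weights.sum())
    pairs = []
    truncated = False
    source_counts: dict[str, int] = {}
    for (name, seq), cnt in zip(copies, counts):
        source_counts[name] = int(cnt)
        for i in range(int(cnt)):
            frag_len = int(rng.integers(spec.fragment_min, spec.fragment_max + 1))
            if frag_len > len(seq):
                frag_len = len(seq)
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            r1 = frag[: spec.read_length]
            r2 = revcomp(frag)[: spec.read_length]
            if len(r1) < spec.read_length:
                truncated = True
            r1 = _sequencing_errors(r1, spec.error_rate, rng)
            r2 = _sequencing_errors(r2, spec.error_rate, rng)
            pairs.append(((f"{name}|p{i}/1", r1), (f"{name}|p{i}/2", r2)))
    return SimulatedReads(pairs, source_counts, truncated)


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    from .search import encode
    arr = encode(seq).copy()
    sites = np.flatnonzero((rng.random(len(arr)) < rate) & (arr != 4))
    if len(sites):
        arr[sites] = (arr[sites] + rng.integers(1, 4, len(sites))) % 4
    return _DNA[np.where(arr == 4, 0, arr)].tobytes().decode()
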