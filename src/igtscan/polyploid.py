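"""Gain/loss reconciliation of transferred genes over a species network.

The default network models two diploid lineages whose internal branches
hybridized to form an allopolyploid ancestor with two descendant leaves:

    root -> A_anc -> A2            (A-lineage diploid)
    root -> D_anc -> D5            (D-lineage diploid)
    {A_anc, D_anc} -> AD -> AD1, AD2   (allopolyploid, union inheritance)

Reconciliation is Dollo: each gene is gained exactly once; absences below
the gain are explained by losses.  Because the allopolyploid nucleus merges
both parental subgenomes, a hybrid node is present when either parent is
present, and losing a gene from the merged genome is a single event — loss
(and decay) events are therefore counted per node, not per incoming edge.
Ties in gain placement break toward the root (the oldest-gain reading of
shared presences); decay placements break toward the leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_ORIGIN = "origin"  # virtual parent of the root, used to name the root gain edge


@dataclass
class SpeciesNetwork:
    """A rooted acyclic species network; hybrid nodes have two parents."""

    nodes: list[str]
    edges: list[tuple[str, str]]  # (parent, child)

    def __post_init__(self) -> None:
        self._parents: dict[str, list[str]] = {n: [] for n in self.nodes}
        self._children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in self.edges:
            self._parents[c].append(p)
            self._children[p].append(c)
        roots = [n for n in self.nodes if not self._parents[n]]
        if len(roots) != 1:
            raise ValueError(f"network must have exactly one root, found {roots}")
        self.root = roots[0]
        for n in self.nodes:
            if n != self.root and len(self._parents[n]) not in (1, 2):
                raise ValueError(f"node {n!r} must have 1 parent (or 2 if hybrid)")
        self._topo = self._topological_sort()

    def _topological_sort(self) -> list[str]:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        order, stack = [], [self.root]
        while stack:
            n = stack.pop(0)
            order.append(n)
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != len(self.nodes):
            raise ValueError("network contains a cycle")
        return order

    @property
    def leaves(self) -> list[str]:
        return [n for n in self._topo if not self._children[n]]

    @property
    def hybrid_nodes(self) -> list[str]:
        return [n for n in self.nodes if len(self._parents[n]) == 2]

    def parents(self, node: str) -> list[str]:
        return list(self._parents[node])

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def topological_nodes(self) -> list[str]:
        return list(self._topo)

    def descendants_or_self(self, node: str) -> set[str]:
        out, stack = set(), [node]
        while stack:
            n = stack.pop()
            if n not in out:
                out.add(n)
                stack.extend(self._children[n])
        return out

    def polyploid_nodes(self) -> set[str]:
        """Hybrid nodes and everything below them."""
        out: set[str] = set()
        for h in self.hybrid_nodes:
            out |= self.descendants_or_self(h)
        return out

    def polyploid_leaves(self) -> list[str]:
        poly = self.polyploid_nodes()
        return [l for l in self.leaves if l in poly]

    def diploid_leaves(self) -> list[str]:
        poly = self.polyploid_nodes()
        return [l for l in self.leaves if l not in poly]

    def gain_edge_label(self, node: str) -> str:
        """Name of the edge (bundle) entering a node."""
        ps = self._parents[node]
        if not ps:
            return f"{_ORIGIN}->{node}"
        return f"{','.join(sorted(ps))}->{node}"

    # --- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"nodes": self.nodes, "edges": [list(e) for e in self.edges]},
                          indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpeciesNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(nodes=list(data["nodes"]),
                   edges=[tuple(e) for e in data["edges"]])


def cotton_network() -> SpeciesNetwork:
    """The default two-diploid + allopolyploid network (leaves A2, D5,
    AD1, AD2)."""
    return SpeciesNetwork(
        nodes=["root", "A_anc", "D_anc", "AD", "A2", "D5", "AD1", "AD2"],
        edges=[("root", "A_anc"), ("root", "D_anc"),
               ("A_anc", "A2"), ("D_anc", "D5"),
               ("A_anc", "AD"), ("D_anc", "AD"),
               ("AD", "AD1"), ("AD", "AD2")])


@dataclass
class EventHistory:
    """Reconstructed single-gain history for one gene."""

    gene: str = ""
    gain_node: str | None = None
    gain_edge: str | None = None
    loss_nodes: list[str] = field(default_factory=list)
    loss_edges: list[str] = field(default_factory=list)
    decay_nodes: list[str] = field(default_factory=list)
    decay_edges: list[str] = field(default_factory=list)
    node_presence: dict[str, bool] = field(default_factory=dict)
    node_state: dict[str, str] = field(default_factory=dict)

    @property
    def n_losses(self) -> int:
        return len(self.loss_nodes)

    @property
    def n_decays(self) -> int:
        return len(self.decay_nodes)


def _loss_count(net: SpeciesNetwork, present: Mapping[str, bool]) -> int:
    """Loss events implied by a node-presence assignment (one event per
    absent node with at least one present parent)."""
    return sum(1 for n in net.nodes
               if not present[n] and any(present[p] for p in net.parents(n)))


def dollo_reconstruct(presence: Mapping[str, bool], net: SpeciesNetwork,
                      gene: str = "") -> EventHistory:
    """Single-gain (Dollo) reconciliation of a leaf presence vector.

    Returns the history minimising the number of loss events; ties in gain
    placement break toward the root.  Presence at a hybrid node follows
    union inheritance (either parent suffices).
    """
    leaves = net.leaves
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise ValueError(f"presence vector missing leaves: {missing}")
    if not any(presence[l] for l in leaves):
        return EventHistory(gene=gene, node_presence={n: False for n in net.nodes})

    present_leaves = {l for l in leaves if presence[l]}
    internal = [n for n in net.topological_nodes() if n not in leaves]
    best: tuple[int, int] | None = None
    best_hist: EventHistory | None = None
    for gi, gain in enumerate(net.topological_nodes()):
        below = net.descendants_or_self(gain)
        if not present_leaves <= below:
            continue
        cand_internal = [n for n in internal if n in below and n != gain]
        for bits in product([True, False], repeat=len(cand_internal)):
            assign = {n: False for n in net.nodes}
            assign[gain] = True
            for n, b in zip(cand_internal, bits):
                assign[n] = b
            for l in leaves:
                assign[l] = presence[l]
            # every present node except the gain needs a present parent
            ok = all(any(assign[p] for p in net.parents(n))
                     for n in net.nodes if assign[n] and n != gain)
            # leaves outside the gain clade cannot be present
            ok = ok and all(not assign[n] or n in below for n in net.nodes)
            if not ok:
                continue
            cost = _loss_count(net, assign)
            key = (cost, gi)
            if best is None or key < best:
                loss_nodes = [n for n in net.topological_nodes()
                              if not assign[n] and any(assign[p] for p in net.parents(n))]
                best = key
                best_hist = EventHistory(
                    gene=gene, gain_node=gain, gain_edge=net.gain_edge_label(gain),
                    loss_nodes=loss_nodes,
                    loss_edges=[net.gain_edge_label(n) for n in loss_nodes],
                    node_presence=assign)
    assert best_hist is not None
    return best_hist


def add_decay_layer(history: EventHistory, states: Mapping[str, str],
                    net: SpeciesNetwork) -> EventHistory:
    """Place irreversible intact->pseudogene decay events on the presence
    layer, minimising their number; ties push decays toward the leaves.

    ``states`` maps each leaf to intact/pseudogene/absent and must be
    consistent with the history's presence layer.
    """
    present = history.node_presence
    leaves = net.leaves
    for l in leaves:
        if states.get(l) == "pseudogene" and not present.get(l, False):
            raise ValueError(f"leaf {l!r} is a pseudogene but absent from the presence layer")
    if history.gain_node is None:
        history.decay_nodes, history.decay_edges = [], []
        return history
    present_internal = [n for n in net.topological_nodes()
                        if present.get(n, False) and n not in leaves]
    fixed = {l: (states[l] == "pseudogene") for l in leaves if present.get(l, False)}
    best_key: tuple[int, int] | None = None
    best_assign: dict[str, bool] | None = None
    for bits in product([False, True], repeat=len(present_internal)):
        pseudo = {n: b for n, b in zip(present_internal, bits)}
        pseudo.update(fixed)
        ok = True
        for n in net.nodes:
            if not present.get(n, False) or pseudo[n]:
                continue
            # an intact node needs an intact present parent (or is the gain)
            if n != history.gain_node and not any(
                    present.get(p, False) and not pseudo[p] for p in net.parents(n)):
                ok = False
                break
        if not ok:
            continue
        transitions = [n for n in net.topological_nodes()
                       if present.get(n, False) and pseudo[n]
                       and (n == history.gain_node
                            or any(present.get(p, False) and not pseudo[p]
                                   for p in net.parents(n)))]
        n_intact = sum(1 for n in present_internal if not pseudo[n])
        key = (len(transitions), -n_intact)
        if best_key is None or key < best_key:
            best_key, best_assign = key, pseudo
    if best_assign is None:
        raise ValueError("leaf states inconsistent with the presence layer")
    transitions = [n for n in net.topological_nodes()
                   if present.get(n, False) and best_assign[n]
                   and (n == history.gain_node
                        or any(present.get(p, False) and not best_assign[p]
                               for p in net.parents(n)))]
    history.decay_nodes = transitions
    history.decay_edges = [net.gain_edge_label(n) if n != history.gain_node
                           else history.gain_edge for n in transitions]
    history.node_state = {
        n: ("absent" if not present.get(n, False)
            else "pseudogene" if best_assign[n] else "intact")
        for n in net.nodes}
    return history


def replay_history(history: EventHistory, net: SpeciesNetwork) -> dict[str, bool]:
    """Forward-propagate a history over the network and return the implied
    leaf presences (round-trip consistency check)."""
    present = {n: False for n in net.nodes}
    if history.gain_node is None:
        return {l: False for l in net.leaves}
    lost = set(history.loss_nodes)
    for n in net.topological_nodes():
        if n == history.gain_node:
            present[n] = True
        elif any(present[p] for p in net.parents(n)) and n not in lost:
            present[n] = True
    return {l: present[l] for l in net.leaves}


# ---------------------------------------------------------------------------
# set operations over per-species transferred-gene sets

def venn_counts(sets: Mapping[str, set[str]]) -> dict[frozenset, int]:
    """Counts of every non-empty intersection region of the species'
    transferred-gene sets (15 regions for 4 species)."""
    species = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    out: dict[frozenset, int] = {}
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            out[frozenset(combo)] = 0
    for gene in universe:
        members = frozenset(sp for sp in species if gene in sets[sp])
        out[members] += 1
    return out


def species_set_from_lists(lists: Iterable[Iterable[str]]) -> tuple[set[str], int, list[str]]:
    """Union of component gene-name lists with duplicate detection.

    Returns (set, count of distinct names, duplicate warnings)."""
    seen: set[str] = set()
    warnings: list[str] = []
    for lst in lists:
        for name in lst:
            if name in seen:
                warnings.append(f"duplicate gene name {name!r} counted once")
            seen.add(name)
    return seen, len(seen), warnings


# ---------------------------------------------------------------------------
# retention asymmetry

@dataclass
class RetentionSummary:
    per_polyploid: dict[str, dict[str, float]]  # leaf -> direction -> retention
    contrast: dict[str, float]                  # leaf -> retention(nupt) - retention(numt)
    count_ratio_range: dict[str, tuple[float, float]]  # direction -> (min, max) diploid/polyploid
    diploid_union_size: dict[str, int]
    undefined: bool = False


def _presence_sets(matrix: pd.DataFrame) -> dict[str, set[str]]:
    return {sp: set(matrix.index[matrix[sp].isin(["intact", "pseudogene"])])
            for sp in matrix.columns}


def retention_asymmetry(numt_matrix: pd.DataFrame, nupt_matrix: pd.DataFrame,
                        net: SpeciesNetwork) -> RetentionSummary:
    """Contrast the survival of diploid-era numts vs nupts in each
    polyploid: retention = |polyploid genes also in >=1 diploid| /
    |genes in >=1 diploid|."""
    diploids = net.diploid_leaves()
    polyploids = net.polyploid_leaves()
    matrices = {"mt_to_nu": numt_matrix, "cp_to_nu": nupt_matrix}
    per_poly: dict[str, dict[str, float]] = {p: {} for p in polyploids}
    union_size: dict[str, int] = {}
    ratio_range: dict[str, tuple[float, float]] = {}
    undefined = False
    for direction, mat in matrices.items():
        sets = _presence_sets(mat)
        dip_union = set().union(*(sets[d] for d in diploids)) if diploids else set()
        union_size[direction] = len(dip_union)
        if not dip_union:
            undefined = True
            for p in polyploids:
                per_poly[p][direction] = float("nan")
            ratio_range[direction] = (float("nan"), float("nan"))
            continue
        for p in polyploids:
            per_poly[p][direction] = len(sets[p] & dip_union) / len(dip_union)
        dip_counts = [len(sets[d]) for d in diploids]
        poly_counts = [len(sets[p]) for p in polyploids]
        if min(poly_counts, default=0) > 0:
            ratio_range[direction] = (min(dip_counts) / max(poly_counts),
                                      max(dip_counts) / min(poly_counts))
        else:
            ratio_range[direction] = (float("nan"), float("nan"))
    contrast = {p: per_poly[p].get("cp_to_nu", float("nan"))
                   - per_poly[p].get("mt_to_nu", float("nan"))
                for p in polyploids}
    return RetentionSummary(per_poly, contrast, ratio_range, union_size, undefined)


def simulate_retention_histories(net: SpeciesNetwork, n_genes: int,
                                 loss_prob_polyploid: float,
                                 rng: np.random.Generator | int = 0,
                                 gene_prefix: str = "g") -> pd.DataFrame:
    """Simulate presence matrices for genes gained at the root with
    independent loss on each polyploid leaf (parameter-recovery harness for
    :func:`retention_asymmetry`)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    diploids, polyploids = net.diploid_leaves(), net.polyploid_leaves()
    rows = {}
    for i in range(n_genes):
        row = {d: "intact" for d in diploids}
        for p in polyploids:
            row[p] = "absent" if rng.random() < loss_prob_polyploid else "intact"
        rows[f"{gene_prefix}{i}"] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(net.leaves)]
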