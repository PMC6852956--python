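import itertools

import numpy as np
import pandas as pd
import pytest

from igtscan.polyploid import (SpeciesNetwork, add_decay_layer, cotton_network,
                               dollo_reconstruct, replay_history,
                               retention_asymmetry, simulate_retention_histories,
                               species_set_from_lists, venn_counts)

from conftest import binom_interval

NET = cotton_network()
LEAVES = NET.leaves


def brute_force_min_losses(presence, net):
    """Oracle: enumerate every (gain node, loss-node subset) and forward
    propagate; return the minimal number of losses for a consistent
    history, or None."""
    nodes = net.topological_nodes()
    best = None
    for gain in nodes:
        for r in range(len(nodes) + 1):
            if best is not None and r >= best:
                break
            for losses in itertools.combinations([n for n in nodes if n != gain], r):
                lost = set(losses)
                present = {}
                for n in nodes:
                    if n in lost:
                        present[n] = False
                    elif n == gain:
                        present[n] = True
                    else:
                        present[n] = any(present[p] for p in net.parents(n))
                if all(present[l] == presence[l] for l in net.leaves):
                    best = r if best is None else min(best, r)
                    break
    return best


def test_network_structure():
    assert NET.root == "root"
    assert NET.hybrid_nodes == ["AD"]
    assert sorted(NET.leaves) == ["A2", "AD1", "AD2", "D5"]
    assert NET.diploid_leaves() == ["A2", "D5"]
    assert NET.polyploid_leaves() == ["AD1", "AD2"]


def test_network_json_roundtrip(tmp_path):
    p = tmp_path / "net.json"
    NET.to_json(p)
    back = SpeciesNetwork.from_json(p)
    assert back.nodes == NET.nodes and back.edges == NET.edges


def test_single_leaf_presence_gains_on_terminal_edge():
    h = dollo_reconstruct({"A2": True, "D5": False, "AD1": False, "AD2": False}, NET)
    assert h.gain_node == "A2" and h.n_losses == 0


def test_diploid_only_presence_needs_one_polyploid_loss():
    h = dollo_reconstruct({"A2": True, "D5": True, "AD1": False, "AD2": False}, NET)
    assert h.gain_node == "root"
    assert h.n_losses == 1 and h.loss_nodes == ["AD"]
    assert brute_force_min_losses(
        {"A2": True, "D5": True, "AD1": False, "AD2": False}, NET) == 1


def test_d_lineage_gain_reaches_both_polyploids_without_loss():
    # the "D5-specific numt present in both polyploids" pattern
    presence = {"A2": False, "D5": True, "AD1": True, "AD2": True}
    h = dollo_reconstruct(presence, NET)
    assert h.gain_node == "D_anc" and h.n_losses == 0
    assert brute_force_min_losses(presence, NET) == 0


def test_all_absent_gives_empty_history():
    h = dollo_reconstruct({l: False for l in LEAVES}, NET)
    assert h.gain_node is None and h.n_losses == 0


def test_dollo_matches_bruteforce_on_every_presence_vector():
    for bits in itertools.product([False, True], repeat=4):
        presence = dict(zip(LEAVES, bits))
        if not any(bits):
            continue
        h = dollo_reconstruct(presence, NET)
        assert h.n_losses == brute_force_min_losses(presence, NET), presence
        # round trip: replaying the history reproduces the leaves
        assert replay_history(h, NET) == presence


def test_gain_tie_breaks_rootward():
    # presence only in both polyploids: gain could sit on AD, AD's parents...
    h = dollo_reconstruct({"A2": False, "D5": False, "AD1": True, "AD2": True}, NET)
    assert h.n_losses == brute_force_min_losses(
        {"A2": False, "D5": False, "AD1": True, "AD2": True}, NET)
    # rootward tie-break: among zero-loss candidates AD is the most rootward
    assert h.gain_node == "AD"


def test_decay_in_both_polyploids_placed_once_at_hybrid():
    presence = {l: True for l in LEAVES}
    h = dollo_reconstruct(presence, NET)
    h = add_decay_layer(h, {"A2": "intact", "D5": "intact",
                            "AD1": "pseudogene", "AD2": "pseudogene"}, NET)
    assert h.decay_nodes == ["AD"]


def test_decay_only_in_one_diploid_is_terminal():
    presence = {l: True for l in LEAVES}
    h = dollo_reconstruct(presence, NET)
    h = add_decay_layer(h, {"A2": "intact", "D5": "pseudogene",
                            "AD1": "intact", "AD2": "intact"}, NET)
    assert h.decay_nodes == ["D5"]


def test_all_intact_no_decay_and_inconsistent_states_raise():
    presence = {l: True for l in LEAVES}
    h = dollo_reconstruct(presence, NET)
    h = add_decay_layer(h, {l: "intact" for l in LEAVES}, NET)
    assert h.decay_nodes == []
    h2 = dollo_reconstruct({"A2": True, "D5": False, "AD1": False, "AD2": False}, NET)
    with pytest.raises(ValueError):
        add_decay_layer(h2, {"A2": "intact", "D5": "pseudogene",
                             "AD1": "absent", "AD2": "absent"}, NET)


def test_decay_minimality_against_bruteforce():
    presence = {l: True for l in LEAVES}
    for bits in itertools.product([False, True], repeat=4):
        states = {l: ("pseudogene" if b else "intact") for l, b in zip(LEAVES, bits)}
        h = dollo_reconstruct(presence, NET)
        h = add_decay_layer(h, states, NET)
        # oracle: enumerate pseudo-labelings of internal present nodes
        internal = [n for n in NET.topological_nodes() if n not in LEAVES]
        best = None
        for ibits in itertools.product([False, True], repeat=len(internal)):
            pseudo = dict(zip(internal, ibits))
            pseudo.update({l: b for l, b in zip(LEAVES, bits)})
            ok = all(pseudo[n] or n == "root"
                     or any(not pseudo[p] for p in NET.parents(n))
                     for n in NET.nodes)
            if not ok:
                continue
            transitions = sum(
                1 for n in NET.nodes if pseudo[n]
                and (n == "root" or any(not pseudo[p] for p in NET.parents(n))))
            best = transitions if best is None else min(best, transitions)
        assert h.n_decays == best, states


def test_venn_counts_examples_and_oracle():
    disjoint = {f"s{i}": {f"g{i}"} for i in range(4)}
    v = venn_counts(disjoint)
    assert sum(v.values()) == 4
    assert all(v[frozenset([f"s{i}"])] == 1 for i in range(4))
    identical = {f"s{i}": {"a", "b", "c"} for i in range(4)}
    v2 = venn_counts(identical)
    assert v2[frozenset(identical)] == 3
    assert sum(v2.values()) == 3
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(40)]
    sets = {f"s{i}": {g for g in genes if rng.random() < 0.4} for i in range(4)}
    v3 = venn_counts(sets)
    # per-element membership oracle
    for combo, count in v3.items():
        expected = sum(
            1 for g in set().union(*sets.values())
            if {s for s in sets if g in sets[s]} == set(combo))
        assert count == expected
    assert sum(v3.values()) == len(set().union(*sets.values()))


def test_published_species_set_counts():
    hirsutum_lists = [["nad9", "ccmFC", "rps10"], ["nad6"],
                      ["nad4", "sdh4", "cob", "cox1", "atp1", "rps14"], ["cox2"]]
    _s, n, warn = species_set_from_lists(hirsutum_lists)
    assert n == 11 and not warn
    barbadense_lists = [["nad9", "ccmFC", "rps10"], ["nad6"],
                        ["nad4L", "cox3", "atp4", "atp6", "mttB"],
                        ["sdh3", "rpl2"], ["nad3", "rps12"]]
    _s, n2, _ = species_set_from_lists(barbadense_lists)
    assert n2 == 13
    assert species_set_from_lists([])[1] == 0
    _s, n3, warn3 = species_set_from_lists([["a"], ["a", "b"]])
    assert n3 == 2 and warn3


def _matrix(rows):
    return pd.DataFrame.from_dict(rows, orient="index")[LEAVES]


def test_retention_all_kept_gives_one_and_zero_contrast():
    rows = {f"g{i}": {l: "intact" for l in LEAVES} for i in range(5)}
    summary = retention_asymmetry(_matrix(rows), _matrix(rows), NET)
    for p in ("AD1", "AD2"):
        assert summary.per_polyploid[p] == {"mt_to_nu": 1.0, "cp_to_nu": 1.0}
        assert summary.contrast[p] == 0.0


def test_published_diploid_polyploid_count_ratio_window():
    # diploid numt counts 33 and 23 vs polyploid 11 and 13
    lo, hi = 23 / 13, 33 / 11
    assert (round(lo, 2), round(hi, 2)) == (1.77, 3.0)
    rows = {}
    for i in range(33):
        rows[f"g{i}"] = {"A2": "intact" if i < 23 else "absent", "D5": "intact",
                         "AD1": "intact" if i < 11 else "absent",
                         "AD2": "intact" if i < 13 else "absent"}
    summary = retention_asymmetry(_matrix(rows), _matrix(rows), NET)
    assert summary.count_ratio_range["mt_to_nu"] == pytest.approx((23 / 13, 33 / 11))


def test_retention_rate_parameter_recovery():
    """Planted polyploid loss rates 0.8 (numts) vs 0.05 (nupts) are
    recovered as retentions 0.2 and 0.95 within binomial 99% intervals."""
    n = 600
    numt = simulate_retention_histories(NET, n, 0.8, rng=1)
    nupt = simulate_retention_histories(NET, n, 0.05, rng=2)
    summary = retention_asymmetry(numt, nupt, NET)
    for p in ("AD1", "AD2"):
        lo, hi = binom_interval(n, 0.2)
        assert lo / n <= summary.per_polyploid[p]["mt_to_nu"] <= hi / n
        lo, hi = binom_interval(n, 0.95)
        assert lo / n <= summary.per_polyploid[p]["cp_to_nu"] <= hi / n
        assert summary.contrast[p] > 0.5
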