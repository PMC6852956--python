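"""Detect planted organelle-to-nucleus insertions in a synthetic genome set.

Simulates the default four-species study, runs the seed-and-extend search
for mitochondrial- and chloroplast-derived nuclear insertions in one
diploid, and compares the merged detections with the planted ground truth.
"""

from igtscan.evaluation import evaluate_recovery
from igtscan.search import merge_hits, search_species, tabulate_directions
from igtscan.simulate import SimulationConfig, simulate_genome_set

sim = simulate_genome_set(SimulationConfig(seed=1))
gs = sim.genome_set

hits = search_species(gs, "A2", directions=["mt_to_nu", "cp_to_nu"])
print(f"{len(hits)} filtered hits in species A2")

for direction in ("mt_to_nu", "cp_to_nu"):
    report = evaluate_recovery(hits, sim.truth, gs, direction, species="A2")
    print(f"{direction}: {report.n_truth} planted insertions, "
          f"recall={report.recall:.3f}, precision={report.precision:.3f}")

summaries = tabulate_directions(gs, hits)
for s in summaries:
    if s.species == "A2" and s.total_length_kb > 0:
        print(f"A2 {s.direction}: {s.total_length_kb:.2f} kb in {s.n_segments} segments")

# recall/precision of 1.0 mean every planted insertion was re-found with
# >=80% reciprocal overlap and nothing was called on clean background; the
# kb totals are the union lengths of merged recipient intervals, the
# Table-1-style tabulation.
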