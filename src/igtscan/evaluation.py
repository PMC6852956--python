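"""Truth-recovery metrics for detection runs on simulated genome sets.

Recall asks whether every planted insertion of a direction is recovered by
a merged detected interval with at least 80% reciprocal overlap.
Precision asks whether each detected interval corresponds to planted
foreign sequence.  A detected interval whose direction differs from the
planted one but which still lies on planted organelle-derived (or
source-pool) sequence is cross-compartment homology — a real property of
the sequences, e.g. a plastid segment that reached the nucleus via the
mitogenome matching both organelles — and is tallied separately rather
than as a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import GenomeSet
from .search import MergedInterval, TransferHit, merge_hits
from .simulate import TruthRecord


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    n_truth: int
    n_detected: int
    n_true_positive: int
    n_cross_talk: int
    n_false_positive: int
    missed: list[str]


def evaluate_recovery(hits: Sequence[TransferHit], truth: Sequence[TruthRecord],
                      genome_set: GenomeSet, direction: str,
                      species: str | None = None,
                      min_reciprocal_overlap: float = 0.8,
                      cluster_gap: int = 500) -> RecoveryReport:
    """Compare detected hits of one direction with the planted truth,
    optionally restricted to one species."""
    dir_hits = [h for h in hits if h.direction == direction]
    merged = merge_hits(dir_hits, cluster_gap)
    dir_truth = [t for t in truth if t.direction == direction
                 and (species is None or t.species == species)]
    # recall: every truth interval recovered by some merged interval
    missed = []
    for t in dir_truth:
        ok = any(m.recipient_seq == t.recipient_seq
                 and reciprocal_overlap((m.start, m.end), t.recipient_interval)
                 >= min_reciprocal_overlap
                 for m in merged)
        if not ok:
            missed.append(t.insertion_id)
    recall = 1.0 - len(missed) / len(dir_truth) if dir_truth else float("nan")
    # precision: every merged interval explained by planted sequence
    planted_any: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        planted_any.setdefault(t.recipient_seq, []).append(t.recipient_interval)
        # donor-side source regions: homology detected "backwards" through
        # them is cross-compartment cross-talk, not a false positive
        planted_any.setdefault(t.donor_seq, []).append((t.donor_start, t.donor_end))
    for f in genome_set.features:
        if f.attributes.get("role") == "nu_to_mt_source" or f.feature_type in ("gene", "tRNA"):
            planted_any.setdefault(f.seq_id, []).append((f.start, f.end))
    tp = xt = fp = 0
    for m in merged:
        same_dir = [t.recipient_interval for t in dir_truth
                    if t.recipient_seq == m.recipient_seq]
        if any(reciprocal_overlap((m.start, m.end), iv) >= min_reciprocal_overlap
               for iv in same_dir):
            tp += 1
        elif any(max(0, min(m.end, iv[1]) - max(m.start, iv[0])) > 0
                 for iv in planted_any.get(m.recipient_seq, ())):
            xt += 1
        else:
            fp += 1
    denom = tp + fp
    precision = tp / denom if denom else float("nan")
    return RecoveryReport(recall, precision, len(dir_truth), len(merged),
                          tp, xt, fp, missed)
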