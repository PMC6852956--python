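"""Donor-side transfer hotspot profiling and plastome-region rates.

Insertions are summarised by the midpoints of their donor source intervals
(midpoints on circular donors are taken modulo the genome length), binned
into fixed-width windows, and — for the plastome — assigned to the
quadripartite regions (LSC, IRa, SSC, IRb) to compute the relative
transfer rate of LSC : IR : SSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .search import TransferHit

DEFAULT_BIN_WIDTH = 10_000


@dataclass
class HotspotProfile:
    donor_seq: str
    bin_width: int
    bin_counts: list[int]
    argmax_bin: tuple[int, int] | None  # None when the profile is empty
    normalized: bool = False

    @property
    def total(self) -> int:
        return int(sum(self.bin_counts))

    def densities_per_bp(self, donor_length: int) -> list[float]:
        out = []
        for i, c in enumerate(self.bin_counts):
            width = min(self.bin_width, donor_length - i * self.bin_width)
            out.append(c / width if width > 0 else 0.0)
        return out


@dataclass
class PlastomePartition:
    """The quadripartite plastome structure as half-open intervals."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]

    def __post_init__(self) -> None:
        ivs = [self.lsc, self.ira, self.ssc, self.irb]
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 != s2:
                raise ValueError("partition intervals must tile the plastome in order")
        if self.lsc[0] != 0:
            raise ValueError("partition must start at 0")
        if (self.ira[1] - self.ira[0]) != (self.irb[1] - self.irb[0]):
            raise ValueError("IRa and IRb must have equal length")

    @property
    def length(self) -> int:
        return self.irb[1]

    def region_of(self, pos: int) -> str:
        for name, (s, e) in (("LSC", self.lsc), ("IRa", self.ira),
                             ("SSC", self.ssc), ("IRb", self.irb)):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside the plastome")


def insertion_midpoints(hits: Sequence[TransferHit],
                        donor_length: int | None = None) -> list[int]:
    """Donor-side middle positions of insertions; circular wrap-around
    intervals are reduced modulo the donor length."""
    out = []
    for h in hits:
        mid = (h.donor_start + h.donor_end) // 2
        if donor_length is not None:
            mid %= donor_length
        out.append(mid)
    return out


def bin_density(midpoints: Sequence[int], donor_length: int,
                bin_width: int = DEFAULT_BIN_WIDTH,
                donor_seq: str = "") -> HotspotProfile:
    """Fixed-width binned frequency profile of donor midpoints; the argmax
    bin breaks ties toward the lowest coordinate and is undefined (None)
    for an empty profile."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = max(1, -(-donor_length // bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for m in midpoints:
        if not (0 <= m < donor_length):
            raise ValueError(f"midpoint {m} outside donor of length {donor_length}")
        counts[m // bin_width] += 1
    if counts.sum() == 0:
        argmax = None
    else:
        i = int(np.argmax(counts))  # first maximum = lowest coordinate
        argmax = (i * bin_width, min((i + 1) * bin_width, donor_length))
    return HotspotProfile(donor_seq, bin_width, counts.tolist(), argmax)


@dataclass
class RegionRates:
    counts: dict[str, int]           # LSC / IR (or IRa,IRb) / SSC
    relative: dict[str, float]       # normalised so LSC = 1 when possible
    per_kb: dict[str, float]
    lsc_normalized: bool             # False when LSC count is zero


def region_rates(hits: Sequence[TransferHit], partition: PlastomePartition,
                 pool_ir: bool = True) -> RegionRates:
    """Assign each hit to the plastome region containing its donor
    midpoint and report counts and relative rates (LSC : IR : SSC)."""
    mids = insertion_midpoints(hits, donor_length=partition.length)
    raw = {"LSC": 0, "IRa": 0, "SSC": 0, "IRb": 0}
    for m in mids:
        raw[partition.region_of(m)] += 1
    if pool_ir:
        counts = {"LSC": raw["LSC"], "IR": raw["IRa"] + raw["IRb"], "SSC": raw["SSC"]}
        lengths = {"LSC": partition.lsc[1] - partition.lsc[0],
                   "IR": (partition.ira[1] - partition.ira[0]) * 2,
                   "SSC": partition.ssc[1] - partition.ssc[0]}
    else:
        counts = raw
        lengths = {"LSC": partition.lsc[1] - partition.lsc[0],
                   "IRa": partition.ira[1] - partition.ira[0],
                   "SSC": partition.ssc[1] - partition.ssc[0],
                   "IRb": partition.irb[1] - partition.irb[0]}
    lsc = counts["LSC"]
    if lsc > 0:
        relative = {k: v / lsc for k, v in counts.items()}
        normalized = True
    else:
        total = sum(counts.values())
        relative = {k: (v / total if total else 0.0) for k, v in counts.items()}
        normalized = False
    per_kb = {k: counts[k] / (lengths[k] / 1000.0) for k in counts}
    return RegionRates(counts, relative, per_kb, normalized)
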