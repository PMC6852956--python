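import numpy as np
import pytest
from scipy import stats

from igtscan.simulate import SimulationConfig, simulate_genome_set


@pytest.fixture(scope="session")
def sim():
    """The default four-species synthetic study, seed 1 (shared; treat as
    read-only)."""
    return simulate_genome_set(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def genome_set(sim):
    return sim.genome_set


def binom_interval(n: int, p: float, alpha: float = 0.01) -> tuple[int, int]:
    """Central (1-alpha) acceptance interval for a Binomial(n, p) count."""
    lo = int(stats.binom.ppf(alpha / 2, n, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


def bitmap_union_length(intervals, size):
    """Brute-force union length via a per-base bitmap (oracle)."""
    bm = np.zeros(size, dtype=bool)
    for s, e in intervals:
        bm[s:e] = True
    return int(bm.sum())
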