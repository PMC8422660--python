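import numpy as np
import pytest

from planrisk import DoseVolumeHistogram


@pytest.fixture
def three_bin_dvh():
    """The worked three-bin curve: cumulative (1, .6, .2, 0) at 0/10/20/30 Gy."""
    return DoseVolumeHistogram(
        "toy", np.array([0.0, 10.0, 20.0, 30.0]),
        np.array([1.0, 0.6, 0.2, 0.0]), 100.0)


@pytest.fixture
def two_level_dvh_factory():
    """DVH with volume fractions at exactly two dose levels (low may be 0)."""
    def make(d_low, d_high, frac_high, name="two-level", total=1.0):
        eps = 1e-7
        edges, cum = [0.0], [1.0]
        if d_low > 0:
            edges += [d_low, d_low + eps]
            cum += [1.0, frac_high]
        else:
            edges += [eps]
            cum += [frac_high]
        edges += [d_high, d_high + eps]
        cum += [frac_high, 0.0]
        return DoseVolumeHistogram(name, np.array(edges), np.array(cum), total)
    return make


def random_dvh(seed, n_points=None, strictly_decreasing=False, max_dose=60.0):
    """Seeded random cumulative DVH for property tests."""
    rng = np.random.default_rng(seed)
    n = n_points or int(rng.integers(3, 40))
    edges = np.sort(rng.uniform(0, max_dose, n - 1))
    edges = np.concatenate([[0.0], edges])
    edges = np.unique(edges)
    while edges.size < 3:
        edges = np.concatenate([edges, [edges[-1] + 1.0]])
    m = edges.size
    if strictly_decreasing:
        drops = rng.uniform(0.05, 1.0, m - 1)
    else:
        drops = rng.uniform(0.0, 1.0, m - 1) * (rng.random(m - 1) < 0.8)
        drops[-1] = max(drops[-1], 0.01)
    cum = 1.0 - np.concatenate([[0.0], np.cumsum(drops)]) / drops.sum()
    cum = np.clip(cum, 0.0, 1.0)
    cum[0] = 1.0
    return DoseVolumeHistogram(f"rand{seed}", edges, cum, float(rng.uniform(10, 2000)))
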