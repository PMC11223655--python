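"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest


def brute_force_gini(degrees) -> float:
    """O(m^2) reference for the degree heterogeneity: half the mean absolute
    difference over all ordered pairs of positive degrees, divided by the
    mean positive degree."""
    x = np.asarray([d for d in degrees if d >= 1], dtype=float)
    m = x.size
    if m == 0:
        raise ValueError("no positive degrees")
    total = 0.0
    for a in x:
        for b in x:
            total += abs(a - b)
    return (total / (m * m)) / (2.0 * x.mean())


def sample_discrete_power_law(gamma, kmin, size, rng, grid_max=100_000):
    """i.i.d. draws from P(k) = k^-gamma / zeta(gamma, kmin), k >= kmin,
    by inverse CDF on a tabulated grid (tail mass beyond grid_max is
    negligible for gamma >= 2.5)."""
    k = np.arange(kmin, grid_max + 1, dtype=float)
    w = k ** (-gamma)
    cdf = np.cumsum(w / w.sum())
    u = rng.random(size)
    return kmin + np.searchsorted(cdf, u, side="left")


def sample_harmonic_tail(size, rng):
    """i.i.d. draws from P(k) = 1/(k (k+1)), k >= 1, via the exact inverse
    CDF: the survival function is P(K >= k) = 1/k, so K = floor(1/U)."""
    u = rng.random(size)
    return np.floor(1.0 / u).astype(np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
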