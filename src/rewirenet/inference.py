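"""Fitting the preferential-attachment proportion p to observed degrees.

With the mean degree kbar pinned to the data (kbar = 2E/N for a static
network; for temporal snapshots E is the snapshot size and N the total
number of nodes in the dataset), the steady-state model has a single free
parameter p.  :func:`fit_p` maximises the log-likelihood of the observed
positive degrees under the closed-form steady-state distribution.  The
model's tail exponent then follows as 1 + 1/p_hat, which can be
cross-checked against a model-free discrete power-law tail fit
(:func:`estimate_tail_exponent`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .meanfield import SteadyStateModel

P_FLOOR = 0.01  # the closed form needs p > 0; smaller p is reported as a boundary fit


@dataclass
class FitResult:
    """Maximum-likelihood fit of the preferential proportion p."""

    p_hat: float
    log_likelihood: float
    kbar: float
    n_obs: int
    boundary: bool = False
    p_grid: np.ndarray | None = None
    log_likelihood_grid: np.ndarray | None = None

    @property
    def gamma_hat(self) -> float:
        return 1.0 + 1.0 / self.p_hat


def profile_log_likelihood(degrees, kbar: float, p_grid) -> np.ndarray:
    """Log-likelihood of the positive degrees under the steady-state model,
    evaluated on a grid of p values."""
    uniq, counts = np.unique(np.asarray(degrees, dtype=np.int64), return_counts=True)
    out = np.empty(len(p_grid))
    for i, p in enumerate(p_grid):
        model = SteadyStateModel(p=float(p), kbar=kbar)
        out[i] = float(np.dot(counts, model.logpmf(uniq)))
    return out


def fit_p(
    degrees,
    kbar: float,
    grid_size: int = 100,
    keep_profile: bool = False,
) -> FitResult:
    """Fit p in [P_FLOOR, 1] by maximum likelihood over the k >= 1 support.

    A 100-point grid locates the maximum, which is then refined by bounded
    scalar optimisation on the bracketing interval; ties break toward larger
    p.  Degenerate inputs (e.g. all degrees equal) drive the optimum to a
    boundary, which is reported via ``boundary=True`` rather than an error.
    """
    x = np.asarray(degrees, dtype=np.int64)
    if x.size < 10:
        raise ValueError(f"need at least 10 positive degrees, got {x.size}")
    if np.any(x < 1):
        raise ValueError("degrees must be >= 1 (drop isolated nodes first)")
    if not kbar > 0:
        raise ValueError("kbar must be > 0")

    uniq, counts = np.unique(x, return_counts=True)

    def nll(p: float) -> float:
        model = SteadyStateModel(p=float(p), kbar=kbar)
        return -float(np.dot(counts, model.logpmf(uniq)))

    grid = np.linspace(P_FLOOR, 1.0, grid_size)
    ll = np.array([-nll(p) for p in grid])
    best = int(len(grid) - 1 - np.argmax(ll[::-1]))  # ties toward larger p
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    p_hat, best_ll = float(res.x), -float(res.fun)
    if ll[best] > best_ll + 1e-12:  # guard against a flat refine interval
        p_hat, best_ll = float(grid[best]), float(ll[best])
    boundary = p_hat >= 1.0 - 1e-3 or p_hat <= P_FLOOR + 1e-3
    if boundary and ll[-1] >= best_ll - 1e-9:
        p_hat, best_ll = 1.0, float(ll[-1])
    return FitResult(
        p_hat=p_hat,
        log_likelihood=best_ll,
        kbar=float(kbar),
        n_obs=int(x.size),
        boundary=boundary,
        p_grid=grid if keep_profile else None,
        log_likelihood_grid=ll if keep_profile else None,
    )


def estimate_tail_exponent(degrees, kmin: int = 10) -> float:
    """Discrete power-law tail exponent by maximum likelihood.

    Observations with k >= kmin are modelled as P(k) = k^-gamma / zeta(gamma,
    kmin) (Hurwitz-zeta normalisation) and the likelihood is maximised
    numerically.  Requires at least 50 tail observations.
    """
    x = np.asarray(degrees, dtype=np.float64)
    tail = x[x >= kmin]
    if tail.size < 50:
        raise ValueError(
            f"need at least 50 observations with k >= {kmin}, got {tail.size}"
        )
    n = tail.size
    sum_log = float(np.log(tail).sum())

    def nll(g: float) -> float:
        return n * np.log(zeta(g, kmin)) + g * sum_log

    res = minimize_scalar(nll, bounds=(1.001, 20.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)
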