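"""Mean-field theory of the rewiring dynamics.

In the limit of large N, E at fixed mean degree kbar = 2E/N, the expected
degree distribution P_t(k) evolves under a deterministic master equation.
Per elementary step, a random node dies (rate 1/N) and its kbar edges (on
average) reattach preferentially (a node of degree k receives an end with
probability k/2E) or at random (probability 1/N per node):

    P_{t+1}(k) = P_t(k) + (1/N) [ -P_t(k)
                                  + p ((k-1) P_t(k-1) - k P_t(k))
                                  + kbar (1-p) (P_t(k-1) - P_t(k)) ]

for k >= 1, with P_t(-1) = 0.  As printed, the equation leaves the killed
node's probability mass unaccounted for; probability conservation forces
the bookkeeping implemented here: a node of degree k >= 1 that dies moves
to degree 0, and degree-0 mass flows up only through the random-attachment
channel (a degree-0 node cannot receive a preferential end), i.e.

    P_{t+1}(0) = P_t(0) + (1/N) [ (1 - P_t(0)) - kbar (1-p) P_t(0) ].

Setting P_{t+1} = P_t yields the steady-state recursion

    P(k) = [p (k-1) + kbar (1-p)] / [1 + p k + kbar (1-p)] * P(k-1),

whose closed-form solution (thermodynamic limit) is a ratio of gamma
functions,

    P(k) = (1/C) * Gamma(k + a) / Gamma(k + a + gamma),
    a = kbar (1/p - 1),     gamma = 1 + 1/p,

normalised over positive degrees k >= 1 by

    C = Gamma(1/p) Gamma(1 + a) / [Gamma(1 + 1/p) Gamma(1 + 1/p + a)].

For k >> kbar/p this falls off as a power law P(k) ~ k^{-gamma} with
scale-free exponent gamma = 1 + 1/p, i.e. any exponent >= 2 depending only
on the proportion p of preferential attachment.  All gamma-function ratios
are evaluated as log-gamma differences, so degrees up to ~1e6 and beyond
are safe from overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .core import SummaryStats


class TruncationError(RuntimeError):
    """Raised when probability mass leaks past kmax faster than tolerated."""


def gamma_exponent(p: float) -> float:
    """Scale-free exponent of the steady-state tail: gamma = 1 + 1/p."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return 1.0 + 1.0 / p


@dataclass(frozen=True)
class SteadyStateModel:
    """The closed-form steady-state degree distribution, parameterised by
    the preferential proportion ``p`` (in (0, 1]) and the mean degree
    ``kbar``.  Supported on k >= 1."""

    p: float
    kbar: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(
                f"p must be in (0, 1] (got {self.p}); the closed form needs 1/p -- "
                "for p = 0 evolve the master equation (master_run) instead"
            )
        if self.kbar < 0:
            raise ValueError("kbar must be >= 0")

    @property
    def a(self) -> float:
        """Offset kbar (1/p - 1) contributed by random attachment."""
        return self.kbar * (1.0 / self.p - 1.0)

    @property
    def gamma(self) -> float:
        return gamma_exponent(self.p)

    @property
    def log_norm(self) -> float:
        """log C with C the normalisation over k >= 1."""
        a, g = self.a, self.gamma
        inv_p = g - 1.0
        return (
            gammaln(inv_p)
            + gammaln(1.0 + a)
            - gammaln(1.0 + inv_p)
            - gammaln(1.0 + inv_p + a)
        )

    def logpmf(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=np.float64)
        out = gammaln(k + self.a) - gammaln(k + self.a + self.gamma) - self.log_norm
        return np.where(k >= 1, out, -np.inf)

    def pmf(self, k) -> np.ndarray:
        return np.exp(self.logpmf(k))

    def survival(self, kmin) -> np.ndarray:
        """P(K >= kmin), via the telescoping tail sum of the gamma-ratio form:
        sum_{k>=K} Gamma(k+a)/Gamma(k+a+g) = Gamma(K+a) / [(g-1) Gamma(K+a+g-1)].
        """
        kmin = np.asarray(kmin, dtype=np.float64)
        log_s = (
            gammaln(kmin + self.a)
            - gammaln(kmin + self.a + self.gamma - 1.0)
            - np.log(self.gamma - 1.0)
            - self.log_norm
        )
        return np.where(kmin <= 1, 1.0, np.exp(log_s))

    def default_kmax(self) -> int:
        return max(1000, int(100 * self.kbar / self.p))


@dataclass
class PmfVector:
    """A degree distribution on k = 0..kmax with the probability lost past
    kmax tracked explicitly; ``sum(probs) + leaked == 1``."""

    probs: np.ndarray
    leaked: float = 0.0

    @property
    def kmax(self) -> int:
        return int(self.probs.size - 1)

    def validate(self, tol: float = 1e-10) -> None:
        if np.any(self.probs < -tol):
            raise ValueError("negative probability entries")
        total = float(self.probs.sum()) + self.leaked
        if abs(total - 1.0) > tol:
            raise ValueError(f"probabilities + leaked = {total}, expected 1")

    def positive_part(self) -> np.ndarray:
        """The distribution conditioned on k >= 1 (renormalised)."""
        q = self.probs.copy()
        q[0] = 0.0
        s = q.sum()
        if s <= 0:
            raise ValueError("no probability mass on k >= 1")
        return q / s


def poisson_pmf_vector(kbar: float, kmax: int) -> PmfVector:
    """Poisson(kbar) initial condition -- the degree law of the random
    initial network in the large-N limit."""
    k = np.arange(kmax + 1)
    probs = poisson.pmf(k, kbar)
    return PmfVector(probs=probs, leaked=float(poisson.sf(kmax, kbar)))


def steady_state_pmf(model: SteadyStateModel, kmax: int | None = None) -> PmfVector:
    """Closed-form steady state on k = 1..kmax (entry 0 is zero); the exact
    tail mass beyond kmax is recorded as ``leaked``."""
    if kmax is None:
        kmax = model.default_kmax()
    probs = np.zeros(kmax + 1)
    probs[1:] = model.pmf(np.arange(1, kmax + 1))
    return PmfVector(probs=probs, leaked=float(model.survival(kmax + 1)))


def sample_steady_state(
    model: SteadyStateModel,
    size: int,
    rng: np.random.Generator,
    grid_max: int = 1 << 16,
) -> np.ndarray:
    """Draw i.i.d. degrees from the closed-form steady state by inverse CDF.

    Degrees up to ``grid_max`` use a tabulated CDF; the (heavy) tail beyond
    is inverted exactly with the closed-form survival function by bisection,
    so even the gamma -> 2 boundary case is sampled without truncation bias.
    """
    cdf = np.cumsum(model.pmf(np.arange(1, grid_max + 1)))
    u = rng.random(size)
    out = 1 + np.searchsorted(cdf, u, side="left")
    in_tail = out > grid_max
    for idx in np.nonzero(in_tail)[0]:
        target = 1.0 - u[idx]  # find smallest K with survival(K+1) <= target
        lo, hi = grid_max, grid_max
        while model.survival(hi + 1) > target:
            lo, hi = hi, hi * 4
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if model.survival(mid + 1) <= target:
                hi = mid
            else:
                lo = mid
        out[idx] = hi
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# master-equation evolution


def master_step(
    P: PmfVector, p: float, kbar: float, N: float, leak_tol: float = 1e-8
) -> PmfVector:
    """One elementary step of the master equation (conservative bookkeeping).

    Mass moves k -> k+1 at rate (p k + kbar (1-p)) / N and k -> 0 at rate
    1/N (death, k >= 1).  Probability is conserved to machine precision up
    to the flux past kmax, which is accumulated into ``leaked``; if a single
    step leaks more than ``leak_tol`` a :class:`TruncationError` asks for a
    larger kmax.
    """
    probs = P.probs
    k = np.arange(probs.size, dtype=np.float64)
    up = (p * k + kbar * (1.0 - p)) * probs / N
    death = probs / N
    death[0] = 0.0
    new = probs - up - death
    new[1:] += up[:-1]
    new[0] += death.sum()
    leak = float(up[-1])
    if leak > leak_tol:
        raise TruncationError(
            f"probability flux {leak:.3e} past kmax={probs.size - 1} exceeds "
            f"{leak_tol:.1e}; increase kmax"
        )
    return PmfVector(probs=new, leaked=P.leaked + leak)


@dataclass
class MasterTrajectory:
    """Master-equation predictions recorded once per network update:
    the full distribution, the expected network size n(t) = N (1 - P_t(0)),
    and the heterogeneity of the k >= 1 part."""

    updates: np.ndarray
    n: np.ndarray
    H: np.ndarray
    pmfs: list[PmfVector] = field(default_factory=list)


def gini_from_pmf(probs: np.ndarray) -> float:
    """Gini coefficient (degree heterogeneity H) of a pmf indexed by
    k = 0..kmax, conditioned on k >= 1."""
    q = np.asarray(probs, dtype=np.float64).copy()
    q[0] = 0.0
    s = q.sum()
    if s <= 0:
        raise ValueError("no probability mass on k >= 1")
    q /= s
    F = np.cumsum(q)
    mean = float(np.dot(np.arange(q.size), q))
    mad = 2.0 * float(np.dot(F, 1.0 - F))
    return mad / (2.0 * mean)


def master_run(
    P0: PmfVector,
    p: float,
    kbar: float,
    N: int,
    n_updates: int,
    record_every: int = 1,
) -> MasterTrajectory:
    """Evolve ``P0`` for ``n_updates`` network updates (one update = N
    elementary master steps), recording every ``record_every`` updates.
    The initial condition is recorded as update 0."""
    if n_updates < 0:
        raise ValueError("n_updates must be >= 0")
    P = PmfVector(P0.probs.copy(), P0.leaked)
    rec_u = [0]
    rec_n = [N * (1.0 - P.probs[0])]
    rec_h = [gini_from_pmf(P.probs)]
    pmfs = [PmfVector(P.probs.copy(), P.leaked)]
    for u in range(1, n_updates + 1):
        for _ in range(N):
            P = master_step(P, p, kbar, N)
        if u % record_every == 0 or u == n_updates:
            rec_u.append(u)
            rec_n.append(N * (1.0 - P.probs[0]))
            rec_h.append(gini_from_pmf(P.probs))
            pmfs.append(PmfVector(P.probs.copy(), P.leaked))
    return MasterTrajectory(
        updates=np.asarray(rec_u),
        n=np.asarray(rec_n),
        H=np.asarray(rec_h),
        pmfs=pmfs,
    )


def master_fixed_point(
    p: float,
    kbar: float,
    kmax: int = 600,
    tol: float = 1e-12,
    max_updates: int = 100_000,
) -> PmfVector:
    """Steady state of the master equation on k >= 1, found by iteration.

    The k >= 1 sector is evolved with its k = 0 coupling folded in
    self-consistently: at stationarity the random-attachment inflow to k = 1,
    kbar (1-p) P(0), exactly balances the death outflow of the whole k >= 1
    sector, so in units of the conditional distribution the source at k = 1
    has rate 1/N per step.  (This limit also covers p = 1, where both P(0)
    -> 1 and the k >= 1 mass vanish but their ratio stays finite.)  The
    distribution is renormalised each step and iterated to a sup-norm change
    below ``tol`` per update.  Truncation is mass-conserving (no flux out of
    kmax), which distorts only the kmax boundary bin.

    This route shares nothing with the closed-form gamma-ratio solution and
    serves as its independent numerical check.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    k = np.arange(kmax + 1, dtype=np.float64)
    b = p * k + kbar * (1.0 - p)  # up-flux rate; b[0] unused
    n_eff = float(b[-1] + 2.0)
    dt = 1.0 / n_eff
    pi = np.zeros(kmax + 1)
    pi[1:] = 1.0 / kmax
    steps_per_update = kmax
    for _ in range(max_updates):
        prev = pi.copy()
        for _ in range(steps_per_update):
            up = b * pi * dt
            up[-1] = 0.0  # conserving truncation
            new = pi - up - pi * dt  # death drains every k >= 1 state
            new[1:] += up[:-1]
            new[1] += dt  # self-consistent inflow from the k = 0 reservoir
            new[0] = 0.0
            pi = new / new.sum()
        if np.max(np.abs(pi - prev)) < tol:
            return PmfVector(probs=pi, leaked=0.0)
    raise RuntimeError(
        f"master-equation fixed point did not converge to {tol} within "
        f"{max_updates} updates (p={p}, kbar={kbar}, kmax={kmax})"
    )


def stationary_isolated_fraction(p: float, kbar: float) -> float:
    """Steady-state probability P(0) that a node is isolated.

    From the k = 0 balance of the conservative master equation: death
    injects mass 1 - P(0) per update, random attachment removes
    kbar (1-p) P(0), hence P(0) = 1 / (1 + kbar (1-p)).  At p = 1 this gives
    P(0) -> 1: with pure preferential attachment the edges condense onto a
    vanishing fraction of hubs.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return 1.0 / (1.0 + kbar * (1.0 - p))


def predicted_stats(model: SteadyStateModel, N: int, E: int) -> SummaryStats:
    """Mean-field steady-state predictions for a finite (N, E) system.

    n = N (1 - P(0)) with P(0) from the master-equation fixed point;
    H is the Gini coefficient of the closed-form k >= 1 distribution,
    truncated at the physical ceiling 2E (no node can exceed degree 2E).
    """
    p0 = stationary_isolated_fraction(model.p, model.kbar)
    kmax = min(model.default_kmax(), 2 * E)
    pmf = steady_state_pmf(model, kmax=kmax)
    return SummaryStats(
        n=N * (1.0 - p0),
        kbar=2.0 * E / N,
        H=gini_from_pmf(pmf.probs),
    )
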