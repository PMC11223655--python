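"""Multigraph state and degree-based summary statistics.

The central object is a network with a *fixed* number of nodes ``N`` and a
fixed number of undirected edges ``E``.  Self-loops and multiedges are legal;
a self-loop contributes 2 to its node's degree, so the handshake identity
``sum(degrees) == 2E`` holds unconditionally.

Summary statistics follow the conventions used throughout the package:

* network size ``n`` -- the number of nodes with at least one connection
  (isolated nodes are invisible in edge-list data, so ``n`` rather than ``N``
  is the observable system size);
* mean degree ``kbar = 2E/N``;
* degree heterogeneity ``H = (1/2) <|k_i - k_j|> / <k>`` computed over
  degrees ``k >= 1``, i.e. the Gini coefficient of the positive degree
  sequence, normalised to lie in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptySupportError(ValueError):
    """Raised when a statistic over positive degrees is requested but no
    node has degree >= 1."""


@dataclass
class MultigraphState:
    """An undirected multigraph with fixed node and edge counts.

    Parameters
    ----------
    N : int
        Total number of nodes.  Node IDs are the contiguous integers
        ``0 .. N-1``.
    edges : ndarray of shape (E, 2), dtype int64
        The edge multiset as unordered endpoint pairs.  During a dynamics
        step an endpoint slot may transiently hold ``-1`` (detached); a
        consistent state never exposes ``-1``.
    degrees : ndarray of shape (N,), dtype int64
        Per-node degree, kept in sync with ``edges``.
    """

    N: int
    edges: np.ndarray
    degrees: np.ndarray

    @classmethod
    def from_edges(cls, N: int, edges) -> "MultigraphState":
        """Build a state from an iterable of (i, j) pairs over ``N`` nodes."""
        N = int(N)
        if N < 1:
            raise ValueError(f"N must be >= 1, got {N}")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= N):
            raise ValueError("edge endpoints must lie in [0, N)")
        degrees = np.bincount(edges.ravel(), minlength=N).astype(np.int64)
        return cls(N=N, edges=edges, degrees=degrees)

    @property
    def E(self) -> int:
        return int(self.edges.shape[0])

    @property
    def kbar(self) -> float:
        """Mean degree 2E/N."""
        return 2.0 * self.E / self.N

    def copy(self) -> "MultigraphState":
        return MultigraphState(self.N, self.edges.copy(), self.degrees.copy())

    def positive_degrees(self) -> np.ndarray:
        """Degrees of the nodes that currently have at least one connection."""
        return self.degrees[self.degrees >= 1]

    def validate(self) -> None:
        """Check internal consistency; raises ``ValueError`` on violation."""
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= self.N):
            raise ValueError("edge endpoints out of range (or detached ends present)")
        recomputed = np.bincount(self.edges.ravel(), minlength=self.N)
        if not np.array_equal(recomputed, self.degrees):
            raise ValueError("degrees inconsistent with edge multiset")
        if int(self.degrees.sum()) != 2 * self.E:
            raise ValueError("degree sum != 2E")


@dataclass
class DegreeDistribution:
    """Empirical degree distribution P(k).

    ``k`` and ``probs`` are aligned arrays; ``counts`` retains the raw
    histogram.  With ``positive_only`` the support is restricted to
    ``k >= 1`` and the probabilities renormalised.
    """

    k: np.ndarray
    probs: np.ndarray
    counts: np.ndarray
    positive_only: bool = False

    def mean(self) -> float:
        return float(np.dot(self.k, self.probs))

    @classmethod
    def from_degrees(cls, degrees, positive_only: bool = False) -> "DegreeDistribution":
        degrees = np.asarray(degrees, dtype=np.int64)
        if degrees.size == 0:
            raise EmptySupportError("no degrees supplied")
        counts = np.bincount(degrees)
        k = np.arange(counts.size)
        if positive_only:
            k, counts = k[1:], counts[1:]
            if counts.sum() == 0:
                raise EmptySupportError(
                    "positive_only requested but every node has degree 0"
                )
        probs = counts / counts.sum()
        return cls(k=k, probs=probs, counts=counts, positive_only=positive_only)


@dataclass
class SummaryStats:
    """Size / density / heterogeneity summary of one network state."""

    n: float       # number of nodes with degree >= 1 (float for model predictions)
    kbar: float    # mean degree 2E/N
    H: float       # Gini coefficient of the positive degree sequence


def degree_distribution(state: MultigraphState, positive_only: bool = False) -> DegreeDistribution:
    """Histogram of node degrees, normalised over the declared support.

    With ``positive_only=True`` the ``k = 0`` bin is dropped before
    normalising (the empirical counterpart of distributions measured from
    edge lists, where isolated nodes are unobservable).
    """
    return DegreeDistribution.from_degrees(state.degrees, positive_only=positive_only)


def heterogeneity(degrees) -> float:
    """Degree heterogeneity H = (1/2) <|k_i - k_j|> / <k> over degrees k >= 1.

    The pair average runs over all ordered pairs (i, j), including i = j,
    which makes H exactly the Gini coefficient of the positive degree
    sequence and bounds it in [0, 1]: H = 0 for a regular graph, H -> 1 when
    a vanishing fraction of hubs holds all the edges.

    Degrees equal to 0 are excluded before averaging.  Raises
    :class:`EmptySupportError` if no degree is >= 1.
    """
    x = np.asarray(degrees)
    if x.size and np.any(x < 0):
        raise ValueError("degrees must be nonnegative")
    x = np.sort(x[x >= 1]).astype(np.float64)
    m = x.size
    if m == 0:
        raise EmptySupportError("heterogeneity needs at least one degree >= 1")
    # mean absolute difference over ordered pairs, via the sorted-sample identity
    i = np.arange(1, m + 1)
    mad = 2.0 * np.dot(2 * i - m - 1, x) / (m * m)
    return float(mad / (2.0 * x.mean()))


def network_size(state: MultigraphState) -> int:
    """Number of nodes with at least one connection."""
    return int(np.count_nonzero(state.degrees))


def summary_stats(state: MultigraphState) -> SummaryStats:
    """(n, kbar, H) of a consistent state."""
    return SummaryStats(
        n=network_size(state),
        kbar=state.kbar,
        H=heterogeneity(state.degrees),
    )
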