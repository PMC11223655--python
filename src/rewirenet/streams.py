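"""Temporal edge streams and their partition into fixed-E snapshots.

A temporal network is recorded as a time-ordered sequence of connections
(i_t, j_t).  Splitting the sequence into consecutive blocks of exactly E
edges yields a series of network snapshots of constant edge count, each
analysed as an undirected multigraph over the dataset's full node space.
A snapshot's size n (nodes with at least one connection) is bounded by 2E
by construction, so snapshots cannot grow without bound even when the
underlying system does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DegreeDistribution,
    MultigraphState,
    SummaryStats,
    summary_stats,
)
from .dynamics import DynamicsConfig, init_random_network, run

logger = logging.getLogger(__name__)


@dataclass
class EdgeStream:
    """A time-ordered sequence of undirected connections.

    ``edges`` holds integer node IDs in [0, n_total); ``labels`` (optional)
    maps each ID back to the original node label; ``times`` (optional) keeps
    the raw timestamps.
    """

    edges: np.ndarray  # (M, 2) int64, in temporal order
    n_total: int
    labels: list | None = None
    times: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.edges.shape[0])


@dataclass
class Snapshot:
    """One block of exactly E consecutive edges, as a multigraph over the
    stream's global node space."""

    index: int
    state: MultigraphState
    stats: SummaryStats


def split_snapshots(stream: EdgeStream, E: int) -> list[Snapshot]:
    """Partition the stream into consecutive non-overlapping blocks of
    exactly ``E`` edges, in stream order.  A trailing remainder of fewer
    than E edges is dropped (and logged), so every snapshot is comparable
    at fixed E.  Repeated (i, j) lines within a block are kept as
    multiedges."""
    E = int(E)
    if E < 1:
        raise ValueError("E must be >= 1")
    M = len(stream)
    n_blocks, dropped = divmod(M, E)
    if n_blocks == 0:
        raise ValueError(f"stream has {M} edges, fewer than the block size E={E}")
    if dropped:
        logger.info("dropping %d trailing edges (< one block of %d)", dropped, E)
    snapshots = []
    for b in range(n_blocks):
        block = stream.edges[b * E : (b + 1) * E]
        state = MultigraphState.from_edges(stream.n_total, block)
        snapshots.append(Snapshot(index=b, state=state, stats=summary_stats(state)))
    return snapshots


def snapshot_trajectories(
    snapshots: list[Snapshot],
) -> tuple[pd.DataFrame, DegreeDistribution]:
    """Per-snapshot (t, n, H) table plus the degree distribution pooled
    across all snapshots (normalised over k >= 1)."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    table = pd.DataFrame(
        {
            "snapshot": [s.index for s in snapshots],
            "n": [s.stats.n for s in snapshots],
            "H": [s.stats.H for s in snapshots],
        }
    )
    pooled = np.concatenate([s.state.positive_degrees() for s in snapshots])
    return table, DegreeDistribution.from_degrees(pooled, positive_only=True)


def pooled_positive_degrees(snapshots: list[Snapshot]) -> np.ndarray:
    """All positive degrees aggregated across snapshots (for fitting)."""
    return np.concatenate([s.state.positive_degrees() for s in snapshots])


def generate_fixture_stream(
    p: float,
    N: int,
    E: int,
    n_snapshots: int,
    seed: int | None = None,
    burn_in_updates: int = 20,
    updates_between: int = 1,
) -> EdgeStream:
    """Synthetic temporal edge stream produced by the model's own dynamics.

    A random network is burned in to steady state, then the current E edges
    are recorded every ``updates_between`` network updates; concatenating
    the blocks gives a stream whose :func:`split_snapshots` recovers
    model-consistent snapshots.  Emulates a stationary temporal dataset.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    config = DynamicsConfig(p=p, seed=seed)
    rng = np.random.default_rng(seed)
    state = init_random_network(N, E, rng=rng)
    run(state, config, n_steps=burn_in_updates * N, rng=rng)
    blocks = [state.edges.copy()]
    for _ in range(n_snapshots - 1):
        run(state, config, n_steps=updates_between * N, rng=rng)
        blocks.append(state.edges.copy())
    return EdgeStream(edges=np.vstack(blocks), n_total=N)
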