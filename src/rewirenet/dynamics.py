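"""Node-death / edge-reattachment dynamics on a fixed-size multigraph.

One elementary step of the dynamics:

1. a node is chosen uniformly at random among all ``N`` nodes (picking an
   isolated node is a legal no-op);
2. each of its incident edge-ends detaches, independently with probability
   ``f`` (the base model has ``f = 1``: the node loses everything);
3. every detached end then reattaches, one after the other: with probability
   ``p`` to a node drawn proportionally to its *current* degree
   (preferential attachment), otherwise to a uniformly random node.

``N`` and ``E`` never change; only the wiring rearranges.  Over many steps
the degree distribution self-organises towards a power law with tail
exponent ``1 + 1/p`` (see :mod:`rewirenet.meanfield`).

Extensions, all off by default except ``f = 1``:

* ``local_info`` -- preferential attachment restricted to the 2-hop
  neighbourhood of the retained endpoint of the detached edge;
* ``allow_multiedges=False`` / ``allow_self_loops=False`` -- reattachment
  rejects targets that would create a parallel edge or a self-loop;
* ``f < 1`` -- fractional edge removal at death.

Implementation notes.  A global preferential draw is realised by sampling a
uniform *edge-end* (target probability k_i / 2E, exactly proportional to
degree) with rejection of transiently detached ends, which keeps a step
O(E) regardless of N.  Detachment happens all at once before any
re-placement, and degrees are updated after each end is re-placed, so later
draws see earlier placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MultigraphState, heterogeneity, network_size

logger = logging.getLogger(__name__)


@dataclass
class DynamicsConfig:
    """Parameters of the rewiring dynamics.

    p : proportion of preferential (vs. uniform-random) attachment, in [0, 1].
    f : fraction of a dying node's edge-ends that detach, in [0, 1]; 1 is the
        base model, 0 freezes the wiring.
    allow_multiedges / allow_self_loops : whether reattachment may create
        parallel edges / self-loops (both allowed in the base model).
    local_info : restrict preferential attachment to the 2-hop neighbourhood
        of the retained endpoint of the edge being rewired.
    seed : RNG seed for :func:`run` / :func:`simulate`.
    """

    p: float
    f: float = 1.0
    allow_multiedges: bool = True
    allow_self_loops: bool = True
    local_info: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")


@dataclass
class TrajectoryRecord:
    """Recorded (t, n, H) samples along one dynamics run, plus optional full
    degree snapshots at requested steps."""

    steps: np.ndarray
    n: np.ndarray
    H: np.ndarray
    degree_snapshots: dict[int, np.ndarray] = field(default_factory=dict)


def init_random_network(
    N: int,
    E: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    allow_multiedges: bool = True,
    allow_self_loops: bool = True,
) -> MultigraphState:
    """Random initial network: E edges with both endpoints uniform on N nodes.

    In the large-N limit the degrees are Poisson(kbar) with kbar = 2E/N.
    With ``allow_multiedges=False`` / ``allow_self_loops=False`` offending
    draws are rejected and redrawn, so the result respects the same
    constraints the dynamics will be run under.
    """
    N, E = int(N), int(E)
    if N < 1 or E < 1:
        raise ValueError(f"N and E must be >= 1, got N={N}, E={E}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if allow_multiedges and allow_self_loops:
        edges = rng.integers(0, N, size=(E, 2))
        return MultigraphState.from_edges(N, edges)
    max_pairs = N * (N - 1) // 2 + (N if allow_self_loops else 0)
    if not allow_multiedges and E > max_pairs:
        raise ValueError(f"cannot place {E} distinct edges on {N} nodes")
    seen: set[tuple[int, int]] = set()
    rows: list[tuple[int, int]] = []
    while len(rows) < E:
        i, j = int(rng.integers(N)), int(rng.integers(N))
        if not allow_self_loops and i == j:
            continue
        key = (i, j) if i <= j else (j, i)
        if not allow_multiedges:
            if key in seen:
                continue
            seen.add(key)
        rows.append((i, j))
    return MultigraphState.from_edges(N, rows)


# ---------------------------------------------------------------------------
# target sampling


def _pair_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def edge_pair_counts(state: MultigraphState) -> dict[tuple[int, int], int]:
    """Multiset of unordered edge pairs (used to enforce no-multiedge runs)."""
    counts: dict[tuple[int, int], int] = {}
    for a, b in state.edges:
        if a >= 0 and b >= 0:
            key = _pair_key(int(a), int(b))
            counts[key] = counts.get(key, 0) + 1
    return counts


def _legal(t: int, other: int, cfg: DynamicsConfig, pair_counts) -> bool:
    if other >= 0:
        if not cfg.allow_self_loops and t == other:
            return False
        if not cfg.allow_multiedges and pair_counts.get(_pair_key(t, other), 0) > 0:
            return False
    return True


def _legal_targets(state, other, cfg, pair_counts) -> np.ndarray:
    ok = np.ones(state.N, dtype=bool)
    if other >= 0:
        if not cfg.allow_self_loops:
            ok[other] = False
        if not cfg.allow_multiedges:
            for (a, b), c in pair_counts.items():
                if c > 0:
                    if a == other:
                        ok[b] = False
                    elif b == other:
                        ok[a] = False
    return np.nonzero(ok)[0]


def local_edge_ends(state: MultigraphState, anchor: int) -> np.ndarray:
    """Attached edge-ends visible from ``anchor`` under local information:
    the ends of every edge incident to the closed 1-hop neighbourhood of
    ``anchor``.  Sampling one uniformly weights each node by its degree
    *counted on locally visible edges*, which restricts the support to
    graph distance <= 2 (e.g. on the path 0-1-2-3-4 with anchor 0 the
    visible edges are (0,1) and (1,2), giving node weights 1:2:1)."""
    edges = state.edges
    m0 = edges[:, 0] == anchor
    m1 = edges[:, 1] == anchor
    nbrs = np.concatenate([edges[m1, 0], edges[m0, 1]])
    nbrs = np.unique(np.append(nbrs[nbrs >= 0], anchor))
    touch = np.isin(edges[:, 0], nbrs) | np.isin(edges[:, 1], nbrs)
    ends = edges[touch].ravel()
    return ends[ends >= 0]


def _draw_preferential_local(state, anchor, other, cfg, rng, pair_counts, cap):
    ends = local_edge_ends(state, anchor)
    if not (cfg.allow_multiedges and cfg.allow_self_loops):
        # the pool is small: restrict to legal ends exactly (identical to
        # rejection sampling, without the pathological all-illegal spin)
        ends = np.array(
            [t for t in ends.tolist() if _legal(t, other, cfg, pair_counts)],
            dtype=np.int64,
        )
    if ends.size == 0:
        return None  # empty/illegal pool -> caller falls back to uniform-random
    return int(ends[int(rng.integers(ends.size))])


def _draw_target(state, r, s, cfg, rng, pair_counts, n_detached):
    """Draw the reattachment target for the detached end (edge r, side s)."""
    edges = state.edges
    other = int(edges[r, 1 - s])  # retained endpoint; -1 if also detached
    # rejection budget before the exact uniform-among-legal fallback
    cap = min(100 * state.N, 10_000)
    if rng.random() < cfg.p:
        if cfg.local_info:
            if other >= 0:
                t = _draw_preferential_local(
                    state, other, other, cfg, rng, pair_counts, cap
                )
                if t is not None:
                    return t
                # zero-degree 2-hop pool: fall through to uniform-random
            else:
                logger.debug(
                    "local preferential draw with no retained endpoint "
                    "(self-loop on the dying node); using global mode"
                )
                t = _draw_preferential_global(
                    state, other, cfg, rng, pair_counts, cap, n_detached
                )
                if t is not None:
                    return t
        else:
            t = _draw_preferential_global(
                state, other, cfg, rng, pair_counts, cap, n_detached
            )
            if t is not None:
                return t
    # random channel (and fallback for empty preferential pools)
    for _ in range(cap):
        t = int(rng.integers(state.N))
        if _legal(t, other, cfg, pair_counts):
            return t
    legal = _legal_targets(state, other, cfg, pair_counts)
    if legal.size == 0:
        raise RuntimeError("no legal reattachment target exists")
    return int(legal[int(rng.integers(legal.size))])


def _draw_preferential_global(state, other, cfg, rng, pair_counts, cap, n_detached):
    """Uniform attached edge-end == degree-proportional node draw.

    Returns None when the attached pool is empty (all ends detached), which
    the caller resolves by uniform-random attachment.
    """
    edges = state.edges
    two_e = edges.size
    if two_e - n_detached <= 0:
        return None
    flat = edges.ravel()
    for _ in range(cap):
        t = int(flat[int(rng.integers(two_e))])
        if t < 0:  # transiently detached slot
            continue
        if _legal(t, other, cfg, pair_counts):
            return t
    legal = _legal_targets(state, other, cfg, pair_counts)
    legal = legal[state.degrees[legal] > 0]
    if legal.size == 0:
        return None
    return int(legal[int(rng.integers(legal.size))])


def sample_attachment_target(
    state: MultigraphState,
    p: float,
    rng: np.random.Generator,
    local_anchor: int | None = None,
    config: DynamicsConfig | None = None,
) -> int:
    """One attachment draw on a fully consistent state (no detached ends).

    With probability ``p``: preferential -- proportional to degree over all
    nodes, or, when ``config.local_info`` and ``local_anchor`` is given, a
    uniform draw over the edge-ends visible from the anchor's closed 1-hop
    set (degree counted on local edges; support within distance 2).
    With probability ``1 - p``: uniform over all N nodes.  Degenerate pools
    (total degree zero, empty neighbourhood) fall back to the uniform draw.
    Multiedge/self-loop constraints are enforced by :func:`step`, not here.
    """
    cfg = config if config is not None else DynamicsConfig(p=p)
    if rng.random() < p:
        if cfg.local_info and local_anchor is not None:
            ends = local_edge_ends(state, int(local_anchor))
            if ends.size > 0:
                return int(ends[int(rng.integers(ends.size))])
        else:
            if state.E > 0 and state.degrees.sum() > 0:
                flat = state.edges.ravel()
                return int(flat[int(rng.integers(flat.size))])
    return int(rng.integers(state.N))


# ---------------------------------------------------------------------------
# the elementary step and full runs


def _death_and_rewire(state, d, cfg, rng, pair_counts) -> None:
    edges = state.edges
    degrees = state.degrees
    rows = np.nonzero((edges[:, 0] == d) | (edges[:, 1] == d))[0]
    ends: list[tuple[int, int]] = []
    for r in rows:
        r = int(r)
        if edges[r, 0] == d:
            ends.append((r, 0))
        if edges[r, 1] == d:
            ends.append((r, 1))
    if cfg.f < 1.0:
        ends = [e for e in ends if rng.random() < cfg.f]
        if not ends:
            return
    # detach all freed ends before any re-placement
    for r, s in ends:
        other = int(edges[r, 1 - s])
        if pair_counts is not None and other >= 0:
            key = _pair_key(d, other)
            pair_counts[key] -= 1
            if pair_counts[key] == 0:
                del pair_counts[key]
        edges[r, s] = -1
        degrees[d] -= 1
    # sequential reattachment; degrees update as ends are re-placed
    n_detached = len(ends)
    for r, s in ends:
        t = _draw_target(state, r, s, cfg, rng, pair_counts, n_detached)
        other = int(edges[r, 1 - s])
        edges[r, s] = t
        degrees[t] += 1
        n_detached -= 1
        if pair_counts is not None and other >= 0:
            key = _pair_key(t, other)
            pair_counts[key] = pair_counts.get(key, 0) + 1


def step(
    state: MultigraphState,
    config: DynamicsConfig,
    rng: np.random.Generator,
    _pair_counts: dict | None = None,
) -> MultigraphState:
    """One elementary step (node death + reattachment), mutating ``state``.

    ``sum(degrees)`` equals ``2E`` both before and after; N and E never
    change.
    """
    if _pair_counts is None and not config.allow_multiedges:
        _pair_counts = edge_pair_counts(state)
    d = int(rng.integers(state.N))
    if state.degrees[d] > 0:
        _death_and_rewire(state, d, config, rng, _pair_counts)
    return state


def run(
    state: MultigraphState,
    config: DynamicsConfig,
    n_steps: int,
    record_every: int | None = None,
    snapshot_at=(),
    rng: np.random.Generator | None = None,
) -> TrajectoryRecord:
    """Apply ``n_steps`` elementary steps, recording (t, n, H) every
    ``record_every`` steps and full degree snapshots at the steps listed in
    ``snapshot_at``.  Reproducible given ``config.seed`` (or an explicit
    ``rng``)."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pair_counts = None if config.allow_multiedges else edge_pair_counts(state)
    snapshot_at = {int(t) for t in snapshot_at}
    rec_t: list[int] = []
    rec_n: list[int] = []
    rec_h: list[float] = []
    snaps: dict[int, np.ndarray] = {}
    degrees = state.degrees
    if n_steps:
        dying = rng.integers(0, state.N, size=n_steps).tolist()
    else:
        dying = []
    for t, d in enumerate(dying, start=1):
        if degrees[d] > 0:
            _death_and_rewire(state, d, config, rng, pair_counts)
        if record_every and t % record_every == 0:
            rec_t.append(t)
            rec_n.append(network_size(state))
            rec_h.append(heterogeneity(degrees))
        if t in snapshot_at:
            snaps[t] = degrees.copy()
    return TrajectoryRecord(
        steps=np.asarray(rec_t, dtype=np.int64),
        n=np.asarray(rec_n, dtype=np.int64),
        H=np.asarray(rec_h, dtype=np.float64),
        degree_snapshots=snaps,
    )


def simulate(
    N: int,
    E: int,
    config: DynamicsConfig,
    n_updates: float,
    record_every_updates: float | None = None,
    snapshot_updates=(),
) -> tuple[MultigraphState, TrajectoryRecord]:
    """Initialise a random network and run ``n_updates`` network updates
    (one update = N elementary steps, so each node dies once on average).

    The initial network honours the multiedge/self-loop permissions of
    ``config``.  Returns the final state and the trajectory record.
    """
    rng = np.random.default_rng(config.seed)
    state = init_random_network(
        N,
        E,
        rng=rng,
        allow_multiedges=config.allow_multiedges,
        allow_self_loops=config.allow_self_loops,
    )
    record_every = int(record_every_updates * N) if record_every_updates else None
    snapshot_at = [int(round(u * N)) for u in snapshot_updates]
    traj = run(
        state,
        config,
        n_steps=int(round(n_updates * N)),
        record_every=record_every,
        snapshot_at=snapshot_at,
        rng=rng,
    )
    return state, traj
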