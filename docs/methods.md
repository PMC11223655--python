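# Methods

## The model

A network of fixed size — `N` nodes, `E` undirected edges (multiedges and
self-loops allowed) — evolves by rewiring. Each elementary step:

1. a node is chosen uniformly at random and "dies": each of its incident
   edge-ends detaches (independently with probability `f`; the base model
   has `f = 1`). Choosing an isolated node is a valid no-op.
2. each detached end reattaches, sequentially: with probability `p` to a
   node drawn proportionally to its current degree (preferential
   attachment), otherwise to a node drawn uniformly among all `N`
   (random attachment).

`N` and `E` are conserved, so the mean degree `k̄ = 2E/N` is fixed. One
*network update* is `N` steps — each node dies once on average. Time in all
trajectory outputs is measured in steps; plots and tables typically use
updates.

Detachment happens in full before any re-placement, and degrees are updated
after each re-placement, so later draws within a step see earlier
placements. The dying node remains a legal target for random attachment and
re-enters the preferential pool as soon as it regains degree (exclusion
effects would be `O(1/N)`). A self-loop on the dying node frees two ends,
each reattached independently.

A global preferential draw is implemented as a uniform draw over attached
edge-ends (probability `k_i / 2E`, exactly proportional to degree), which
makes a step `O(E)` and the whole simulation independent of `N` except for
the uniform draws. The public `sample_attachment_target` uses the same rule
via explicit degree weights; the two routes are compared by frequency tests.

### Extensions

- **Local information** (`local_info=True`): the preferential channel sees
  only the edges incident to the closed 1-hop neighbourhood of the retained
  endpoint of the edge being rewired, and draws a uniform edge-end among
  them — i.e. nodes are weighted by their degree *as locally visible*,
  which restricts the support to graph distance ≤ 2 (on the path
  0–1–2–3–4 with anchor 0 the visible edges are (0,1) and (1,2), giving
  weights 1:2:1 on nodes 0, 1, 2). The random channel stays global. When
  the edge being rewired has no attached retained endpoint (a self-loop on
  the dying node), the draw falls back to the global rule. Rationale for
  anchoring on the retained endpoint: the dying node has just lost its
  neighbourhood, so the surviving endpoint is the only locality reference
  the edge has.
- **Simple-graph constraints** (`allow_multiedges=False`,
  `allow_self_loops=False`): reattachment draws are rejected while they
  would create a parallel edge or self-loop (cap `100·N` attempts, then a
  uniform draw among the exactly-enumerated legal targets; an error if none
  exists). The initial network honours the same constraints.
- **Fractional removal** (`f < 1`): each incident end detaches
  independently with probability `f`, a smooth interpolation whose limits
  recover the frozen network (`f = 0`) and the base model (`f = 1`).

## Mean-field theory

For large `N, E` at fixed `k̄`, the expected degree distribution obeys, per
step and for `k ≥ 1`,

    P_{t+1}(k) = P_t(k) + (1/N) [ −P_t(k)
                 + p((k−1)P_t(k−1) − kP_t(k))
                 + k̄(1−p)(P_t(k−1) − P_t(k)) ].

Probability conservation forces the `k = 0` bookkeeping: death moves a
degree-`k ≥ 1` node to degree 0, and degree-0 mass leaves only through the
random channel (a degree-0 node cannot receive a preferential end):

    P_{t+1}(0) = P_t(0) + (1/N) [ (1 − P_t(0)) − k̄(1−p) P_t(0) ].

`master_step` implements exactly this flux form (up-rate
`p·k + k̄(1−p)` per `1/N`, death rate `1/N`), conserving total mass to
machine precision apart from the flux past the truncation degree `kmax`,
which is accumulated in `leaked` and raises a `TruncationError` if a single
step loses more than `1e-8`.

Setting `P_{t+1} = P_t` gives the recursion

    P(k) / P(k−1) = [p(k−1) + k̄(1−p)] / [1 + pk + k̄(1−p)],

solved in closed form by a ratio of gamma functions,

    P(k) = (1/C) Γ(k + a) / Γ(k + a + γ),   a = k̄(1/p − 1),  γ = 1 + 1/p,

normalised over `k ≥ 1` by
`C = Γ(1/p)Γ(1+a) / [Γ(1+1/p)Γ(1+1/p+a)]`. For `k ≫ k̄/p` this is a power
law `k^(−γ)` with scale-free exponent `γ = 1 + 1/p ∈ [2, ∞)`. At `p = 1`
the ratios telescope to `P(k) = 1/(k(k+1))` with `C = 1` exactly. All
gamma ratios are evaluated as `gammaln` differences (safe to `k ~ 1e6+`),
and the truncated tail mass is computed exactly from the telescoping
survival function `P(K ≥ k) = (1/C) Γ(k+a) / [(γ−1) Γ(k+a+γ−1)]`, so
truncation never needs iterative enlargement.

### Numerical fixed point and the p = 1 limit

`master_fixed_point` iterates the `k ≥ 1` sector of the master equation
with its `k = 0` coupling folded in self-consistently. At stationarity the
inflow to `k = 1`, `k̄(1−p)P(0)`, equals the total death outflow of the
`k ≥ 1` sector, so in conditional units the source at `k = 1` has rate
exactly 1 per update-per-node; this form is regular at `p = 1`, where the
full chain condenses (`P(0) → 1`, all edge mass escaping to unbounded
degrees) and the naive conditional becomes 0/0. The iteration uses a
mass-conserving truncation (no flux out of `kmax`), which provably distorts
only the boundary bin — interior ratios still satisfy the stationary
recursion exactly — so comparisons against the closed form renormalise over
`k = 1..kmax−1`. Uniform step size `1/(b(kmax)+2)` guarantees positivity;
convergence is declared at sup-norm change `< 1e-12` per update (measured
agreement with the closed form ~1e-14).

### Predicted summary statistics

- Isolated fraction: `P(0) = 1/(1 + k̄(1−p))` from the `k = 0` balance;
  predicted network size `n = N(1 − P(0))`. At `p = 1` this degenerates to
  `n → 0` — the condensation limit; finite simulations show a small
  positive `n` held by a few giant hubs.
- Heterogeneity `H`: the Gini coefficient of the closed-form `k ≥ 1`
  distribution, computed from the CDF identity
  `E|X−X'| = 2 Σ_k F(k)(1−F(k))`. The distribution is truncated at the
  physical ceiling `min(kmax_default, 2E)` — no node can exceed degree
  `2E` — which also regularises the `γ ≤ 2` infinite-mean boundary.

## Summary statistics

- network size `n`: nodes with degree ≥ 1 (isolated nodes are invisible in
  edge-list data).
- heterogeneity `H = (1/2)⟨|k_i − k_j|⟩/⟨k⟩` over degrees `k ≥ 1`, with the
  pair average over all ordered pairs including `i = j`: this makes `H`
  exactly the Gini coefficient of the positive degree sequence, bounded in
  `[0, 1]` (0 for regular graphs, → 1 under hub domination). Conventions
  that exclude `i = j` or use unordered pairs differ by `O(1/m)`;
  comparisons against simulated ensembles absorb that.

## Inference

With `k̄` pinned to the data (`2E/N`; for temporal snapshots `E` is the
snapshot size and `N` the dataset's total node count), the steady-state
family has the single parameter `p`. `fit_p` maximises
`Σ log P(k_i; p, k̄)` over the `k ≥ 1` support — the canonical
one-parameter fit, using every observation rather than only the tail — on a
100-point grid over `[0.01, 1]` refined by bounded scalar optimisation,
ties broken toward larger `p`. The floor `p = 0.01` exists because the
closed form needs `p > 0`; fits at either end are flagged `boundary` rather
than erroring (degenerate inputs such as all-equal degrees land there).

`estimate_tail_exponent` is the standard discrete power-law MLE:
`P(k) = k^(−γ)/ζ(γ, kmin)` on `k ≥ kmin`, maximised numerically. A caveat
quantified during development and relevant to interpreting results: the
gamma-ratio law approaches its `k^(−γ)` asymptote slowly (local log-log
slope at `k = 10` for `p = 0.5, k̄ = 0.1` is −2.74, not −3), so at
`kmin = 10` the estimator's population value is ≈ 2.86 rather than 3.0; it
converges to `1 + 1/p` as `kmin` grows. Tests and the reproduction script
use `kmin = 10` with tolerances that accommodate this known finite-`kmin`
bias only to the extent their stated bands allow.

## Temporal streams

A time-ordered edge sequence is split into consecutive non-overlapping
blocks of exactly `E` edges; a trailing remainder is dropped (logged) so
all snapshots are comparable at fixed `E` (default `E = 1e3`). Each block
is a multigraph over the dataset's full node space — repeated lines are
multiedges, self-pairs count degree 2 — giving `n ≤ 2E` by construction.
`generate_fixture_stream` emulates a stationary temporal dataset with the
model's own dynamics: burn-in of 20 updates, then the current edge set
recorded every update. What it does *not* emulate: non-stationarity
(growth, regime shifts), timestamp burstiness, directedness, and node-label
churn of real datasets — passing stream tests therefore demonstrates
self-consistency of the pipeline, not that any particular real system
follows the model.

## Problem sizes and determinism

The reference system throughout is `N = 2e4`, `E = 1e3` (`k̄ = 0.1`,
matching the regime of sparse temporal snapshots), run for 10–15 updates,
which trajectory traces show is past the `n` and `H` plateaus; denser
checks use `N = 2e3, E = 1e3` (`k̄ = 1`). Ensembles of 10–50 replicates
back trend assertions; the tail-exponent check pools 400 final states to
pin the MLE to ~0.03. Every stochastic path takes an explicit integer seed
(one `numpy` Generator per run; replicate banks via `SeedSequence`), so all
outputs, including CLI tables, are byte-reproducible.

## Known limitations

- The mean-field equation ignores degree correlations and finite-size
  cutoffs; at `p → 1` the stationary theory predicts condensation, while
  finite simulations equilibrate to a few-hub state whose `n` and `H`
  depend on `E`.
- `predicted_stats` heterogeneity at `γ ≤ 2.2` depends visibly on the `2E`
  truncation (the untruncated mean diverges at `γ ≤ 2`); this is a modelling
  choice, not a numerical artefact.
- The fitting machinery assumes stationarity of the observed degrees; the
  sparse-limit closed forms for `n(p)` and `H(p)` are not implemented
  (numeric evaluation of the closed-form distribution covers that ground).
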