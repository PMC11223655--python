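"""The death-and-reattachment dynamics and its extensions."""

import numpy as np
import pytest

from rewirenet.core import MultigraphState, heterogeneity, network_size
from rewirenet.dynamics import (
    DynamicsConfig,
    init_random_network,
    run,
    sample_attachment_target,
    simulate,
    step,
)


class TestInitRandomNetwork:
    def test_mean_degree_is_fixed_by_counts(self):
        state = init_random_network(200, 10, seed=0)
        assert state.kbar == pytest.approx(0.1)
        state.validate()

    def test_single_node_forces_self_loops(self):
        state = init_random_network(1, 3, seed=0)
        assert state.degrees[0] == 6
        assert np.all(state.edges == 0)

    @pytest.mark.parametrize("N, E", [(0, 5), (5, 0), (-1, 2)])
    def test_nonpositive_sizes_rejected(self, N, E):
        with pytest.raises(ValueError):
            init_random_network(N, E)

    def test_isolated_fraction_matches_binomial_oracle(self):
        # each node avoids all 2E independent endpoint draws with
        # probability (1 - 1/N)^(2E); compare over 100 replicates
        N, E, reps = 10_000, 1_000, 100
        rng = np.random.default_rng(42)
        p0_exact = (1.0 - 1.0 / N) ** (2 * E)
        fracs = []
        for _ in range(reps):
            state = init_random_network(N, E, rng=rng)
            fracs.append(np.mean(state.degrees == 0))
        se = np.sqrt(p0_exact * (1 - p0_exact) / N / reps)
        assert abs(np.mean(fracs) - p0_exact) < 3 * se

    def test_simple_graph_init_respects_constraints(self):
        state = init_random_network(
            50, 120, seed=1, allow_multiedges=False, allow_self_loops=False
        )
        pairs = [tuple(sorted(e)) for e in state.edges.tolist()]
        assert len(set(pairs)) == len(pairs)
        assert all(a != b for a, b in pairs)

    def test_infeasible_simple_graph_rejected(self):
        with pytest.raises(ValueError):
            init_random_network(4, 20, allow_multiedges=False, allow_self_loops=False)


class TestAttachmentTarget:
    def test_preferential_probabilities_proportional_to_degree(self, rng):
        # degrees (2, 1, 1) -> target probabilities (0.5, 0.25, 0.25)
        state = MultigraphState.from_edges(3, [(0, 1), (0, 2)])
        draws = np.array(
            [sample_attachment_target(state, p=1.0, rng=rng) for _ in range(100_000)]
        )
        freq = np.bincount(draws, minlength=3) / draws.size
        assert np.allclose(freq, [0.5, 0.25, 0.25], atol=0.01)

    def test_random_attachment_ignores_degrees(self, rng):
        state = MultigraphState.from_edges(5, [(0, 0)] * 4)  # node 0 hoards all degree
        draws = np.array(
            [sample_attachment_target(state, p=0.0, rng=rng) for _ in range(100_000)]
        )
        freq = np.bincount(draws, minlength=5) / draws.size
        assert np.allclose(freq, 0.2, atol=0.01)

    def test_local_preferential_restricted_to_two_hops(self, rng):
        # path 0-1-2-3-4, anchor 0: support {0,1,2}, weights prop. to (1,2,1)
        state = MultigraphState.from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        cfg = DynamicsConfig(p=1.0, local_info=True)
        draws = np.array(
            [
                sample_attachment_target(state, p=1.0, rng=rng, local_anchor=0, config=cfg)
                for _ in range(100_000)
            ]
        )
        freq = np.bincount(draws, minlength=5) / draws.size
        assert np.allclose(freq[:3], [0.25, 0.5, 0.25], atol=0.01)
        assert freq[3] == 0 and freq[4] == 0

    def test_zero_degree_pool_falls_back_to_uniform(self, rng):
        state = MultigraphState.from_edges(4, np.empty((0, 2), dtype=np.int64))
        draws = np.array(
            [sample_attachment_target(state, p=1.0, rng=rng) for _ in range(20_000)]
        )
        freq = np.bincount(draws, minlength=4) / draws.size
        assert np.allclose(freq, 0.25, atol=0.02)


class TestStep:
    def test_degree_sum_conserved_step_by_step(self, rng):
        state = init_random_network(300, 200, rng=rng)
        cfg = DynamicsConfig(p=0.7)
        for _ in range(500):
            step(state, cfg, rng)
            assert state.degrees.sum() == 2 * state.E
        state.validate()

    def test_counts_invariant_under_runs(self):
        for seed, p, f in [(0, 0.2, 1.0), (1, 0.9, 0.5), (2, 1.0, 1.0)]:
            state = init_random_network(400, 300, seed=seed)
            run(state, DynamicsConfig(p=p, f=f, seed=seed), n_steps=5_000)
            assert state.N == 400 and state.E == 300
            state.validate()

    def test_constraint_flags_hold_after_every_step(self, rng):
        cfg = DynamicsConfig(p=0.8, allow_multiedges=False, allow_self_loops=False)
        state = init_random_network(
            40, 80, rng=rng, allow_multiedges=False, allow_self_loops=False
        )
        for _ in range(400):
            step(state, cfg, rng)
            pairs = [tuple(sorted(e)) for e in state.edges.tolist()]
            assert len(set(pairs)) == len(pairs)
            assert all(a != b for a, b in pairs)


class TestRun:
    def test_zero_steps_is_identity(self):
        state = init_random_network(50, 30, seed=3)
        before = state.edges.copy()
        traj = run(state, DynamicsConfig(p=0.5, seed=3), n_steps=0)
        assert np.array_equal(state.edges, before)
        assert traj.steps.size == 0

    def test_reproducible_given_seed(self):
        out = []
        for _ in range(2):
            state, traj = simulate(500, 200, DynamicsConfig(p=0.6, seed=11), 5,
                                   record_every_updates=1)
            out.append((state.edges.copy(), traj.n.copy(), traj.H.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])
        assert np.array_equal(out[0][2], out[1][2])

    def test_f1_matches_default_trajectory(self):
        a, _ = simulate(300, 150, DynamicsConfig(p=0.5, seed=7), 5)
        b, _ = simulate(300, 150, DynamicsConfig(p=0.5, f=1.0, seed=7), 5)
        assert np.array_equal(a.edges, b.edges)

    def test_f0_freezes_degrees(self):
        state = init_random_network(500, 300, seed=1)
        before = state.degrees.copy()
        run(state, DynamicsConfig(p=0.7, f=0.0, seed=2), n_steps=3_000)
        assert np.array_equal(before, state.degrees)

    def test_preferential_attachment_shrinks_network(self):
        # hubs absorb edges, so n drops below the random-graph value on
        # average (a trend over replicates, not per run)
        n0, n1 = [], []
        for s in range(20):
            state = init_random_network(2_000, 1_000, seed=s)
            n0.append(network_size(state))
            run(state, DynamicsConfig(p=0.9, seed=s), n_steps=10 * 2_000)
            n1.append(network_size(state))
        assert np.mean(n1) < np.mean(n0)

    def test_more_preferential_means_smaller_and_more_heterogeneous(self):
        stats = {}
        for p in (0.1, 0.9):
            ns, hs = [], []
            for s in range(10):
                state, _ = simulate(2_000, 1_000, DynamicsConfig(p=p, seed=s), 10)
                ns.append(network_size(state))
                hs.append(heterogeneity(state.degrees))
            stats[p] = (np.mean(ns), np.mean(hs))
        assert stats[0.9][0] < stats[0.1][0]
        assert stats[0.9][1] > stats[0.1][1]
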