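"""Block-model machinery: pair factors, H, Metropolis kernel, posteriors."""

import numpy as np
import pytest
from scipy.integrate import quad

import oracles
from ddiblocks import (
    InteractionNetwork,
    Partition,
    SamplerConfig,
    build_view,
    coclassification_matrix,
    compute_H,
    link_type_posterior,
    log_pair_factor,
    prism_predict,
    run_sampler,
    score_all_pairs,
)
from ddiblocks.sbm import SampleSet, _ChainState
from conftest import random_network


class TestLogPairFactor:
    def test_empty_counts_give_log_one(self):
        assert log_pair_factor([0, 0]) == 0.0
        assert log_pair_factor([0, 0, 0, 0]) == 0.0

    def test_binary_single_count_matches_quadrature(self):
        # K=2, counts (1,0): integral of p over [0,1] = 1/2
        assert log_pair_factor([1, 0]) == pytest.approx(np.log(0.5))
        val, _ = quad(lambda p: p**3 * (1 - p) ** 2, 0, 1)
        assert log_pair_factor([3, 2]) == pytest.approx(np.log(val))

    def test_k3_matches_monte_carlo_simplex_integration(self, rng):
        mc = oracles.dirichlet_factor_mc([1, 1, 0], rng)
        assert np.exp(log_pair_factor([1, 1, 0])) == pytest.approx(
            1 / 12, rel=1e-12
        )
        assert mc == pytest.approx(1 / 12, rel=0.01)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_pair_factor([1, -1])

    def test_prior_constant_switch(self):
        with_c = log_pair_factor([2, 1, 0])
        without = log_pair_factor([2, 1, 0], include_prior_constant=False)
        assert with_c - without == pytest.approx(np.log(2.0))


class TestComputeH:
    def test_zero_observations_gives_zero_h_for_any_partition(self, k3_alphabet):
        net = InteractionNetwork("ABCDE", k3_alphabet, {})
        view = build_view(net)
        for assignment in ([0, 0, 0, 0, 0], [0, 1, 2, 3, 4], [0, 1, 0, 1, 0]):
            p = Partition.from_assignment(view, assignment)
            assert compute_H(p) == 0.0

    def test_block_structured_partition_beats_random_one(self, toy_net):
        view = build_view(toy_net)
        good = Partition.from_assignment(view, [0, 0, 0, 1, 1, 1])
        scrambled = Partition.from_assignment(view, [0, 1, 0, 1, 0, 1])
        assert compute_H(good) < compute_H(scrambled)

    def test_matches_independent_oracle(self, toy_net):
        view = build_view(toy_net)
        edges = list(zip(view.u, view.v, view.t))
        for assignment in ([0, 0, 0, 1, 1, 1], [0, 1, 2, 3, 4, 5], [2, 2, 1, 1, 0, 0]):
            p = Partition.from_assignment(view, assignment)
            assert compute_H(p) == pytest.approx(
                oracles.h_of_assignment(assignment, edges, 3), abs=1e-10
            )


class TestMetropolisKernel:
    def test_incremental_h_equals_recount_along_a_chain(self, rng):
        net = random_network(rng, n_drugs=9, k=3, density=0.5)
        view = build_view(net)
        state = _ChainState(view, rng.integers(0, 9, 9))
        for step in range(300):
            state.step(rng)
            if step % 50 == 0:
                scratch = compute_H(Partition.from_assignment(view, state.g))
                assert state.h == pytest.approx(scratch, abs=1e-10)

    def test_seeded_chains_replay_exactly(self, toy_net):
        view = build_view(toy_net)

        def run(seed):
            r = np.random.default_rng(seed)
            s = _ChainState(view, r.integers(0, 6, 6))
            for _ in range(200):
                s.step(r)
            return s.g.copy(), s.h

        g1, h1 = run(7)
        g2, h2 = run(7)
        assert np.array_equal(g1, g2) and h1 == h2

    def test_flat_h_proposals_always_accepted(self, k3_alphabet, rng):
        # no observations: every move has dH = 0 and must be accepted
        net = InteractionNetwork("ABCDE", k3_alphabet, {})
        state = _ChainState(build_view(net), rng.integers(0, 5, 5))
        assert all(state.step(rng) for _ in range(100))


class TestSampler:
    def test_pooled_sample_count_matches_protocol(self, toy_net):
        cfg = SamplerConfig(n_chains=3, samples_per_chain=5, seed=1)
        ss = run_sampler(toy_net, cfg)
        assert ss.n_samples == 15
        assert ss.assignments.shape == (15, 6)

    def test_same_seed_reproduces_samples_bitwise(self, toy_net):
        cfg = SamplerConfig(n_chains=2, samples_per_chain=10, seed=42)
        s1 = run_sampler(toy_net, cfg)
        s2 = run_sampler(toy_net, cfg)
        assert np.array_equal(s1.assignments, s2.assignments)
        assert np.array_equal(s1.h_values, s2.h_values)

    def test_empty_network_samples_have_h_zero(self, k3_alphabet):
        net = InteractionNetwork("ABCD", k3_alphabet, {})
        ss = run_sampler(net, SamplerConfig(n_chains=1, samples_per_chain=1, seed=0))
        assert ss.n_samples == 1
        assert ss.h_values[0] == 0.0


class TestLinkTypePosterior:
    def test_no_evidence_gives_uniform_posterior(self, k3_alphabet):
        net = InteractionNetwork("ABCD", k3_alphabet, {})
        ss = run_sampler(net, SamplerConfig(n_chains=1, samples_per_chain=5, seed=0))
        probs = link_type_posterior(ss, ("A", "B"))
        assert probs == pytest.approx(np.ones(3) / 3)

    def test_matches_exhaustive_enumeration_on_toy_network(self, toy_net):
        view = build_view(toy_net)
        edges = list(zip(view.u, view.v, view.t))
        queries = [(0, 5), (1, 4), (2, 3)]  # the unobserved pairs
        exact = oracles.exact_posteriors(6, edges, 3, queries)
        ss = run_sampler(toy_net, SamplerConfig(n_chains=10, samples_per_chain=100, seed=3))
        for (i, j), expected in exact.items():
            got = link_type_posterior(ss, (toy_net.drugs[i], toy_net.drugs[j]))
            assert np.abs(got - expected).max() < 0.02

    def test_posteriors_are_normalized(self, rng):
        net = random_network(rng, n_drugs=7, k=4, density=0.5)
        scores = score_all_pairs(net, SamplerConfig(n_chains=2, samples_per_chain=20, seed=5))
        assert len(scores) == 21
        for probs in scores.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_label_invariance_under_order_preserving_renaming(self, toy_net):
        cfg = SamplerConfig(n_chains=3, samples_per_chain=30, seed=8)
        renamed = InteractionNetwork(
            [f"Z{d}" for d in toy_net.drugs],
            toy_net.alphabet,
            {(f"Z{a}", f"Z{b}"): t for (a, b), t in toy_net.observations().items()},
        )
        p1 = link_type_posterior(run_sampler(toy_net, cfg), ("A", "F"))
        p2 = link_type_posterior(run_sampler(renamed, cfg), ("ZA", "ZF"))
        assert np.array_equal(p1, p2)

    def test_exact_posterior_invariant_under_arbitrary_relabeling(self, toy_net):
        view = build_view(toy_net)
        edges = list(zip(view.u, view.v, view.t))
        perm = [3, 0, 5, 1, 4, 2]  # drug i -> position perm[i]
        edges_p = [(perm[u], perm[v], t) for u, v, t in edges]
        exact = oracles.exact_posteriors(6, edges, 3, [(0, 5)])
        exact_p = oracles.exact_posteriors(6, edges_p, 3, [(perm[0], perm[5])])
        assert exact[(0, 5)] == pytest.approx(
            exact_p[(perm[0], perm[5])], abs=1e-9
        )

    def test_added_consistent_evidence_raises_that_types_posterior(self, k3_alphabet):
        # groups {A,B},{C,D}; growing between-group evidence of type 2
        base = {("A", "B"): 1, ("C", "D"): 1}
        history = []
        for extra in (
            {},
            {("A", "C"): 2},
            {("A", "C"): 2, ("B", "D"): 2},
            {("A", "C"): 2, ("B", "D"): 2, ("B", "C"): 2},
        ):
            net = InteractionNetwork("ABCD", k3_alphabet, {**base, **extra})
            view = build_view(net)
            edges = list(zip(view.u, view.v, view.t))
            post = oracles.exact_posteriors(4, edges, 3, [(0, 3)])[(0, 3)]
            history.append(post[2])
        assert all(b > a for a, b in zip(history, history[1:]))

    def test_leave_self_out_removes_the_scored_pairs_own_observation(self):
        # one observed pair, fully observed binary view: scoring that pair
        # must not let its own edge inflate the estimate
        from ddiblocks import BINARY

        net = InteractionNetwork("AB", BINARY, {("A", "B"): 1})
        ss = run_sampler(
            net, SamplerConfig(n_chains=1, samples_per_chain=10, seed=0),
            mode="fully_observed",
        )
        probs = link_type_posterior(ss, ("A", "B"))
        # after removing the pair's own edge no evidence remains: uniform
        assert probs == pytest.approx([0.5, 0.5])


class TestCoclassification:
    def test_single_sample_gives_indicator_matrix(self, toy_net):
        view = build_view(toy_net)
        g = np.array([0, 0, 1, 1, 2, 2])
        ss = SampleSet(
            view=view,
            assignments=g[None, :].astype(np.int32),
            h_values=np.zeros(1),
            n_chains=1,
        )
        c = coclassification_matrix(ss)
        assert np.array_equal(c, (g[:, None] == g[None, :]).astype(float))
        assert np.all(np.diag(c) == 1.0)

    def test_block_structure_separates_within_from_between(self, toy_net):
        ss = run_sampler(toy_net, SamplerConfig(n_chains=5, samples_per_chain=50, seed=2))
        c = coclassification_matrix(ss)
        g = np.array([0, 0, 0, 1, 1, 1])
        within = (g[:, None] == g[None, :]) & ~np.eye(6, dtype=bool)
        between = g[:, None] != g[None, :]
        # on a network this small the posterior keeps real mass on split
        # partitions, so the contrast is clear but not extreme
        assert c[within].mean() > 2 * c[between].mean()
        assert c[within].mean() - c[between].mean() > 0.15
        assert np.allclose(c, c.T)


class TestEstimatorIdentity:
    def test_single_partition_average_equals_prism_estimator(self, toy_net):
        view = build_view(toy_net)
        assignment = [0, 0, 0, 1, 1, 1]
        part = Partition.from_assignment(view, assignment)
        ss = SampleSet(
            view=view,
            assignments=np.asarray(assignment, dtype=np.int32)[None, :],
            h_values=np.zeros(1),
            n_chains=1,
        )
        for pair in [("A", "F"), ("B", "E"), ("C", "D")]:
            sbm_probs = link_type_posterior(ss, pair)
            prism_probs = prism_predict(part, toy_net, pair)
            assert sbm_probs == pytest.approx(prism_probs, abs=1e-12)


class TestTraceSerialization:
    def test_trace_round_trips_through_json(self, toy_net, tmp_path):
        import json

        ss = run_sampler(toy_net, SamplerConfig(n_chains=1, samples_per_chain=5, seed=0))
        p = tmp_path / "trace.json"
        ss.save_trace(p)
        rec = json.loads(p.read_text())
        assert rec["drugs"] == list(toy_net.drugs)
        assert len(rec["h"]) == 5
        assert np.array_equal(np.asarray(rec["assignments"]), ss.assignments)


class TestFullyObservedScoring:
    def test_dense_block_non_edges_outscore_sparse_block_non_edges(self):
        from ddiblocks import planted_binary_network, score_all_pairs

        net, assignment = planted_binary_network(60, 2, p_in=0.7, p_out=0.05, seed=8)
        scores = score_all_pairs(
            net,
            SamplerConfig(n_chains=3, samples_per_chain=60, seed=2, thinning=2),
            mode="fully_observed",
        )
        edges = net.edge_set()
        within, between = [], []
        for (a, b), probs in scores.items():
            if (a, b) in edges:
                continue
            (within if assignment[a] == assignment[b] else between).append(probs[1])
        # closed form under the planted partition: (n1+1)/(n+2) ~ block density
        assert np.mean(within) > 0.5 > np.mean(between)
        assert min(within) > max(between)


class TestThermalizationGuard:
    def test_burnin_cap_warns_or_raises(self, rng):
        # a cap too small for the equilibration window test to ever pass
        net = random_network(rng, n_drugs=8, k=3, density=0.8)
        lax = SamplerConfig(
            n_chains=1, samples_per_chain=2, seed=0, burnin_cap=5, thinning=1
        )
        with pytest.warns(Warning):
            run_sampler(net, lax)
        strict = SamplerConfig(
            n_chains=1, samples_per_chain=2, seed=0, burnin_cap=5,
            thinning=1, strict_thermalization=True,
        )
        with pytest.raises(RuntimeError):
            run_sampler(net, strict)
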