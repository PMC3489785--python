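import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmaxbp import bp_core as bp
from hmaxbp.bp_core import (ApproximationConfig, ConfigError,
                            DegenerateEvidenceError, StructuralError,
                            TreeNetwork)


def dirichlet_tree(rng, max_nodes=10, max_k=6, max_joint=3e5):
    """Random singly-connected network with Dirichlet(1) tables."""
    n = int(rng.integers(3, max_nodes + 1))
    ks = rng.integers(2, max_k + 1, size=n)
    while np.prod(ks.astype(float)) > max_joint:
        ks[rng.integers(n)] = 2
    parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    cpt = []
    for i in range(n):
        if parent[i] < 0:
            cpt.append(rng.dirichlet(np.ones(ks[i])))
        else:
            cpt.append(rng.dirichlet(np.ones(ks[i]), size=ks[parent[i]]).T)
    tree = TreeNetwork(parent, [int(k) for k in ks], cpt)
    evidence = {i: rng.uniform(0.01, 1.0, size=ks[i])
                for i in range(n) if rng.random() < 0.6}
    return tree, evidence


class TestFloorAndRenormalize:
    @pytest.mark.parametrize("d,eps,expected", [
        ([0.25, 0.25, 0.25, 0.25], 1e-6, [0.25, 0.25, 0.25, 0.25]),
        ([1.0, 0.0], 0.01, [0.99, 0.01]),
        ([0.5, 0.5, 0.0, 0.0], 0.01, [0.49, 0.49, 0.01, 0.01]),
    ])
    def test_examples(self, d, eps, expected):
        out = bp.floor_and_renormalize(np.array(d), eps)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_floor_too_large_rejected(self):
        with pytest.raises(ConfigError):
            bp.floor_and_renormalize(np.array([0.5, 0.5]), 0.6)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8)
           .filter(lambda v: sum(v) > 1e-3),
           st.floats(1e-9, 1e-2))
    @settings(max_examples=100, deadline=None)
    def test_result_is_floored_distribution(self, vals, eps):
        d = np.array(vals) / sum(vals)
        if eps >= 1.0 / len(d):
            return
        out = bp.floor_and_renormalize(d, eps)
        assert out.min() >= eps - 1e-15
        assert abs(out.sum() - 1.0) < 1e-9

    def test_batched_rows_match_single(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(5), size=7)
        rows[0, :2] = 0
        rows[0] /= rows[0].sum()
        batch = bp.floor_and_renormalize(rows, 1e-3)
        for r in range(7):
            np.testing.assert_allclose(
                batch[r], bp.floor_and_renormalize(rows[r], 1e-3),
                atol=1e-12)


class TestMaxLambdaCount:
    def test_documented_values(self):
        assert bp.max_lambda_count(4, 1e308, 1e-6) == 51
        assert bp.max_lambda_count(2, 1e308, 0.5) == 1023

    def test_infinite_ceiling_is_unbounded(self):
        assert bp.max_lambda_count(4, math.inf, 1e-6) == math.inf

    def test_bound_is_sharp_against_worst_case(self):
        # the normalisation constant of N floored messages is at most
        # eps^-N; N_max must keep that below r_max, N_max+1 need not
        r_max, eps = 1e100, 1e-7
        n = bp.max_lambda_count(3, r_max, eps)
        assert eps ** (-n) <= r_max < eps ** (-(n + 1))


class TestSelectTopVariance:
    def test_ranks_by_entry_variance(self):
        msgs = [np.array([0.5, 0.5]), np.array([0.9, 0.1]),
                np.array([0.7, 0.3])]
        assert set(bp.select_top_variance(msgs, 2)) == {1, 2}

    def test_n_at_least_length_returns_all(self):
        msgs = [np.array([0.5, 0.5]), np.array([0.9, 0.1])]
        assert sorted(bp.select_top_variance(msgs, 5)) == [0, 1]

    def test_tie_breaks_to_lower_index(self):
        m = np.array([0.6, 0.4])
        assert bp.select_top_variance([m, m.copy()], 1) == [0]

    def test_empty_list(self):
        assert bp.select_top_variance([], 3) == []


class TestCombineLambda:
    CFG = ApproximationConfig(eps_min=1e-9)

    def test_uniform_messages_stay_uniform(self):
        u = np.full(4, 0.25)
        np.testing.assert_allclose(bp.combine_lambda([u, u], self.CFG), u)

    def test_toy_node_product(self):
        m = np.array([0.9, 0.5, 0.5, 0.1, 0.5, 0.5])
        raw = np.array([0.729, 0.125, 0.125, 0.001, 0.125, 0.125])
        out = bp.combine_lambda([m, m, m], self.CFG)
        np.testing.assert_allclose(out, raw / raw.sum(), rtol=1e-6)

    def test_single_message_identity(self):
        m = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(bp.combine_lambda([m], self.CFG), m,
                                   atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        msgs = list(rng.dirichlet(np.ones(5), size=6))
        a = bp.combine_lambda(msgs, self.CFG)
        b = bp.combine_lambda(msgs[::-1], self.CFG)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            bp.combine_lambda([np.ones(3) / 3, np.ones(4) / 4], self.CFG)

    def test_matches_exact_product_when_under_bound(self):
        rng = np.random.default_rng(7)
        msgs = list(rng.dirichlet(np.ones(4), size=5))
        exact = np.prod(msgs, axis=0)
        exact /= exact.sum()
        np.testing.assert_allclose(
            bp.combine_lambda(msgs, ApproximationConfig(eps_min=1e-12)),
            exact, atol=1e-9)


class TestLambdaToParent:
    def test_toy_s1_to_c1_printed_message(self, toy):
        cpt = toy.model.cpts["S1"][0, 0]
        out = bp.lambda_to_parent(np.array([0.9, 0.1]), cpt)
        np.testing.assert_allclose(out, [0.9, 0.5, 0.5, 0.1, 0.5, 0.5])

    def test_uniform_lambda_gives_uniform_message(self):
        rng = np.random.default_rng(0)
        cpt = rng.dirichlet(np.ones(3), size=5).T  # columns normalised
        out = bp.lambda_to_parent(np.full(3, 1 / 3), cpt)
        np.testing.assert_allclose(out, np.full(5, 1 / 3), atol=1e-12)

    def test_toy_c1_to_s2_printed_message(self, toy):
        cpt = toy.model.cpts["C1"][0, 0]
        lam = np.array([0.75, 0.05, 0.05, 0.05, 0.05, 0.05])
        out = bp.normalize(bp.lambda_to_parent(lam, cpt))
        np.testing.assert_allclose(np.round(out, 2), [0.46, 0.08, 0.46])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            bp.lambda_to_parent(np.ones(3) / 3, np.ones((2, 4)) / 2)


class TestCombinePi:
    EXACT = bp.EXACT

    def test_delta_parent_selects_column(self):
        rng = np.random.default_rng(1)
        cpt = rng.dirichlet(np.ones(4), size=3).T
        delta = np.array([0.0, 1.0, 0.0])
        out = bp.combine_pi([delta], [cpt], self.EXACT)
        np.testing.assert_allclose(out, cpt[:, 1] / cpt[:, 1].sum())

    def test_uniform_parent_gives_row_means(self):
        cpt = np.array([[0.9, 0.4], [0.1, 0.6]])
        out = bp.combine_pi([np.array([0.5, 0.5])], [cpt], self.EXACT)
        expected = cpt.mean(axis=1)
        np.testing.assert_allclose(out, expected / expected.sum())

    def test_two_identical_parents_match_one(self):
        rng = np.random.default_rng(2)
        cpt = rng.dirichlet(np.ones(4), size=5).T
        pi = rng.dirichlet(np.ones(5))
        one = bp.combine_pi([pi], [cpt], self.EXACT)
        two = bp.combine_pi([pi, pi], [cpt, cpt], self.EXACT)
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_single_parent_no_sampling_is_matvec(self):
        rng = np.random.default_rng(4)
        cpt = rng.dirichlet(np.ones(6), size=7).T
        pi = rng.dirichlet(np.ones(7))
        out = bp.combine_pi([pi], [cpt], self.EXACT)
        np.testing.assert_allclose(out, (cpt @ pi) / (cpt @ pi).sum(),
                                   atol=1e-12)

    def test_count_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            bp.combine_pi([np.ones(2) / 2], [], self.EXACT)


class TestBelief:
    def test_uniform_pi_returns_lambda(self):
        lam = np.array([0.8, 0.2])
        np.testing.assert_allclose(bp.belief(lam, np.array([0.5, 0.5])),
                                   lam)

    def test_uniform_lambda_returns_pi(self):
        pi = np.array([0.3, 0.7])
        np.testing.assert_allclose(bp.belief(np.array([0.5, 0.5]), pi), pi)

    def test_contradictory_evidence_raises(self):
        with pytest.raises(DegenerateEvidenceError):
            bp.belief(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


class TestPiToChild:
    def test_message_is_the_belief(self):
        bel = np.array([0.7, 0.3])
        np.testing.assert_allclose(bp.pi_to_child(bel), bel)

    def test_clamped_delta_propagates(self):
        d = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(bp.pi_to_child(d), d)

    def test_exact_message_excluding_uniform_child_equals_belief_rule(self):
        # when the excluded child's message is flat, dropping the
        # exclusion (the belief approximation) changes nothing
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(4))
        lams = [rng.dirichlet(np.ones(4)), np.full(4, 0.25),
                rng.dirichlet(np.ones(4))]
        exact = bp.pi_to_child_exact(pi, lams, 1)
        full = pi * lams[0] * lams[2]
        np.testing.assert_allclose(exact, full / full.sum(), atol=1e-12)

    def test_belief_approximation_error_is_bounded_by_one_message(self):
        # the approximate message multiplies in exactly one extra factor
        rng = np.random.default_rng(6)
        pi = rng.dirichlet(np.ones(3))
        lams = list(rng.dirichlet(np.ones(3), size=3))
        exact = bp.pi_to_child_exact(pi, lams, 0)
        approx_raw = exact * lams[0]
        approx = approx_raw / approx_raw.sum()
        bel = pi * np.prod(lams, axis=0)
        np.testing.assert_allclose(bp.pi_to_child(bel / bel.sum()), approx,
                                   atol=1e-12)


class TestExactOracle:
    def test_single_root_prior_is_its_belief(self):
        p = np.array([0.2, 0.8])
        tree = TreeNetwork([-1], [2], [p])
        np.testing.assert_allclose(bp.exact_bp_marginals(tree)[0], p)
        np.testing.assert_allclose(bp.enumerate_marginals(tree)[0], p)

    def test_two_node_chain_matches_enumeration(self):
        rng = np.random.default_rng(8)
        cpt = rng.dirichlet(np.ones(3), size=2).T
        tree = TreeNetwork([-1, 0], [2, 3], [np.array([0.6, 0.4]), cpt])
        ev = {1: np.array([0.9, 0.05, 0.05])}
        for a, b in zip(bp.enumerate_marginals(tree, ev),
                        bp.exact_bp_marginals(tree, ev)):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_random_trees_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree, ev = dirichlet_tree(rng, max_joint=1e4)
            for a, b in zip(bp.enumerate_marginals(tree, ev),
                            bp.exact_bp_marginals(tree, ev)):
                np.testing.assert_allclose(a, b, atol=1e-9)

    def test_non_topological_order_refused(self):
        with pytest.raises(StructuralError):
            TreeNetwork([1, -1], [2, 2], [None, None])


class TestKlDivergence:
    def test_zero_on_identical(self):
        p = np.array([0.3, 0.7])
        assert bp.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_positive_on_different(self):
        assert bp.kl_divergence(np.array([0.9, 0.1]),
                                np.array([0.5, 0.5])) > 0


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(eps_min=0.0), dict(eps_min=1.5), dict(r_max=0.5),
        dict(m_pi=0), dict(m_states=0),
        dict(parent_weights_rule="learned"),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ApproximationConfig(**kwargs)
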