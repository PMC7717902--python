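"""Poisson strata model, conditional binomial test, tree rescaling, BM reconstruction."""

import math

import dendropy
import numpy as np
import pytest
from scipy import optimize
from scipy.integrate import quad

from pabscan import simulate as sim
from pabscan import stratatest as strata

from conftest import random_binary_newick


class TestPoissonPmf:
    def test_zero_count_closed_form(self):
        assert strata.poisson_strata_pmf(0, 0.5, 5.0) == pytest.approx(math.exp(-2.5))

    def test_zero_rate_degenerate(self):
        assert strata.poisson_strata_pmf(0, 0.0, 10.0) == 1.0
        assert strata.poisson_strata_pmf(3, 0.0, 10.0) == 0.0

    def test_normalization(self):
        total = sum(strata.poisson_strata_pmf(k, 1.0, 2.5) for k in range(200))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            strata.poisson_strata_pmf(-1, 1.0, 1.0)


class TestConditionalBinomialTest:
    def test_published_per_my_value(self):
        p = strata.conditional_binomial_test(3, 0, 188.52, 321.32)
        assert p == pytest.approx(0.0506, abs=5e-4)
        assert round(p, 3) == 0.051

    def test_published_per_generation_value(self):
        p = strata.conditional_binomial_test(3, 0, 44.23, 158.52)
        assert p == pytest.approx(0.0104, abs=5e-4)
        assert round(p, 3) == 0.010

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_fair_coin(self, k):
        assert strata.conditional_binomial_test(k, 0, 100.0, 100.0) == pytest.approx(0.5**k)

    def test_no_events_no_evidence(self):
        assert strata.conditional_binomial_test(0, 0, 10.0, 20.0) == 1.0

    def test_scale_invariance(self):
        a = strata.conditional_binomial_test(2, 3, 10.0, 30.0)
        b = strata.conditional_binomial_test(2, 3, 1000.0, 3000.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_in_s1_at_fixed_total(self):
        ps = [strata.conditional_binomial_test(s1, 6 - s1, 50.0, 70.0) for s1 in range(7)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_two_sided_at_least_one_sided(self):
        one = strata.conditional_binomial_test(3, 0, 188.52, 321.32)
        two = strata.conditional_binomial_test(3, 0, 188.52, 321.32, alternative="two-sided")
        assert two >= one

    def test_matches_monte_carlo_conditional_draws(self):
        rng = np.random.default_rng(0)
        n = 100_000
        for _ in range(5):
            s1, s2 = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            if s1 + s2 == 0:
                s1 = 1
            dt1, dt2 = rng.uniform(10, 300, size=2)
            p_exact = strata.conditional_binomial_test(s1, s2, dt1, dt2)
            draws = rng.binomial(s1 + s2, dt1 / (dt1 + dt2), size=n)
            p_mc = (draws >= s1).mean()
            se = math.sqrt(max(p_mc * (1 - p_mc), 1e-9) / n)
            assert abs(p_exact - p_mc) < 3 * se + 1e-12

    def test_negative_lengths_rejected(self):
        with pytest.raises(ValueError):
            strata.conditional_binomial_test(1, 0, -1.0, 2.0)


class TestGenerationsOnBranch:
    def test_constant_gamma_limit(self):
        assert strata.generations_on_branch(0.0, 10.0, 5.0, 5.0) == pytest.approx(2.0)

    def test_linear_gamma_closed_form(self):
        g = strata.generations_on_branch(0.0, 1e7, 5.0, 10.0)
        assert g == pytest.approx(2e6 * math.log(2), rel=1e-12)

    def test_symmetric_in_endpoint_exchange(self):
        a = strata.generations_on_branch(0.0, 7.0, 3.0, 11.0)
        b = strata.generations_on_branch(0.0, 7.0, 11.0, 3.0)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("rel", [1e-3, 1e-6, 1e-9])
    def test_near_equal_endpoints_approach_limit(self, rel):
        g = strata.generations_on_branch(0.0, 10.0, 5.0, 5.0 * (1 + rel))
        assert g == pytest.approx(10.0 / 5.0, rel=2 * rel)

    def test_matches_quadrature_on_random_branches(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ta = rng.uniform(0, 50)
            td = ta + rng.uniform(0.1, 50)
            ga, gd = rng.uniform(1, 25, size=2)
            exact = strata.generations_on_branch(ta, td, ga, gd)
            num, _ = quad(lambda t: 1.0 / (ga + (gd - ga) * (t - ta) / (td - ta)), ta, td)
            assert exact == pytest.approx(num, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            strata.generations_on_branch(0.0, 1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            strata.generations_on_branch(2.0, 1.0, 1.0, 2.0)


def brute_force_bm(newick: str, tips: dict[str, float]) -> dict[str, float]:
    """Numerically maximize the joint BM log-density over internal states."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        edges.append((node.parent_node, node, node.edge.length))

    def value(node, x):
        if node.is_leaf():
            return tips[node.taxon.label]
        return x[internal.index(node)]

    def neg_log_density(x):
        return sum((value(c, x) - value(p, x)) ** 2 / (2 * t) for p, c, t in edges)

    x0 = np.full(len(internal), np.mean(list(tips.values())))
    res = optimize.minimize(neg_log_density, x0, method="BFGS", tol=1e-14)
    return {
        (n.label or f"node{i}"): float(v) for i, (n, v) in enumerate(zip(internal, res.x))
    }


FIXTURE_NEWICK = "((A:1.5,B:2.0)N1:1.0,((C:0.8,D:1.2)N2:0.6,E:2.5)N3:0.9)R;"
FIXTURE_TIPS = {"A": 3.0, "B": 5.0, "C": 10.0, "D": 8.0, "E": 2.0}
# reference values from an independent GLS/re-rooting implementation of the
# same estimator (phytools::fastAnc), frozen at development time
FIXTURE_EXPECTED = {
    "R": 5.5341727845,
    "N1": 4.6311566698,
    "N3": 6.3468872878,
    "N2": 7.9319499057,
}


class TestBmAncestralStates:
    @staticmethod
    def by_label(result):
        return {n.label: v for n, v in result.items()}

    def test_two_tip_symmetry(self):
        res = self.by_label(
            strata.bm_ancestral_states(
                strata.TimedTree("(A:1.0,B:1.0)R;"), {"A": 4.0, "B": 8.0}
            )
        )
        assert res["R"] == pytest.approx(6.0)

    def test_star_tree_is_mean(self):
        res = self.by_label(
            strata.bm_ancestral_states(
                strata.TimedTree("(A:1.0,B:1.0,C:1.0,D:1.0)R;"),
                {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0},
            )
        )
        assert res["R"] == pytest.approx(2.5)

    def test_matches_independent_reference_values(self):
        res = self.by_label(
            strata.bm_ancestral_states(strata.TimedTree(FIXTURE_NEWICK), FIXTURE_TIPS)
        )
        for label, expected in FIXTURE_EXPECTED.items():
            assert res[label] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_matches_brute_force_likelihood_maximization(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        newick = random_binary_newick(n_tips, rng)
        tips = {f"t{i}": float(rng.uniform(0, 10)) for i in range(n_tips)}
        ours = strata.bm_ancestral_states(strata.TimedTree(newick), tips)
        brute = brute_force_bm(newick, tips)
        ours_vals = sorted(ours.values())
        brute_vals = sorted(brute.values())
        np.testing.assert_allclose(ours_vals, brute_vals, atol=1e-6)

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError, match="B"):
            strata.bm_ancestral_states(strata.TimedTree("(A:1.0,B:1.0)R;"), {"A": 1.0})

    def test_zero_branch_length_rejected(self):
        with pytest.raises(ValueError):
            strata.bm_ancestral_states(
                strata.TimedTree("(A:0.0,B:1.0)R;"), {"A": 1.0, "B": 2.0}
            )


class TestRescaleTree:
    def test_uniform_gamma_divides_lengths(self):
        tt = strata.TimedTree(
            "((A:1.5,B:2.0):1.0,C:2.5)R;", tip_ages={"A": 4.0, "B": 4.0, "C": 4.0}
        )
        rs = strata.rescale_tree_to_generations(tt)
        for orig, new in zip(
            tt.tree.preorder_node_iter(), rs.tree.preorder_node_iter()
        ):
            if orig.parent_node is None:
                continue
            assert new.edge.length == pytest.approx(orig.edge.length / 4.0)

    def test_single_branch_matches_generations_on_branch(self):
        # two tips with distinct ages: each terminal branch integrates the
        # linear gamma between the reconstructed root age and the tip age
        tt = strata.TimedTree("(A:10.0,B:10.0)R;", tip_ages={"A": 4.0, "B": 8.0})
        anc = strata.bm_ancestral_states(tt, tt.tip_ages)
        root_gamma = next(iter(anc.values()))
        rs = strata.rescale_tree_to_generations(tt)
        new_lengths = {
            n.taxon.label: n.edge.length for n in rs.tree.leaf_node_iter()
        }
        assert new_lengths["A"] == pytest.approx(
            strata.generations_on_branch(0.0, 10.0, root_gamma, 4.0)
        )
        assert new_lengths["B"] == pytest.approx(
            strata.generations_on_branch(0.0, 10.0, root_gamma, 8.0)
        )

    def test_total_matches_per_branch_quadrature(self):
        rng = np.random.default_rng(7)
        newick = random_binary_newick(6, rng)
        ages = {f"t{i}": float(rng.uniform(2, 12)) for i in range(6)}
        tt = strata.TimedTree(newick, tip_ages=ages)
        anc = strata.bm_ancestral_states(tt, ages)
        times = tt.node_times()

        def gamma_of(node):
            if node.is_leaf():
                return ages[node.taxon.label]
            return anc[node]

        total_quad = 0.0
        for node in tt.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ta, td = times[node.parent_node], times[node]
            ga, gd = gamma_of(node.parent_node), gamma_of(node)
            val, _ = quad(lambda t: 1.0 / (ga + (gd - ga) * (t - ta) / (td - ta)), ta, td)
            total_quad += val
        rs = strata.rescale_tree_to_generations(tt)
        total_ours = sum(
            n.edge.length for n in rs.tree.preorder_node_iter() if n.parent_node
        )
        assert total_ours == pytest.approx(total_quad, rel=1e-6)

    def test_topology_and_tips_preserved(self):
        tt = strata.TimedTree(
            FIXTURE_NEWICK, tip_ages={k: v + 2 for k, v in FIXTURE_TIPS.items()}
        )
        rs = strata.rescale_tree_to_generations(tt)
        assert sorted(rs.tip_labels()) == sorted(tt.tip_labels())
        assert (
            tt.tree.as_string(schema="newick", suppress_edge_lengths=True)
            == rs.tree.as_string(schema="newick", suppress_edge_lengths=True)
        )

    def test_missing_age_names_tip(self):
        tt = strata.TimedTree("(A:1.0,B:1.0)R;", tip_ages={"A": 4.0})
        with pytest.raises(ValueError, match="B"):
            strata.rescale_tree_to_generations(tt)


class TestStrataRateAnalysis:
    def test_published_totals_reproduce_both_p_values(self):
        _, p_my = strata.strata_rate_analysis(3, 0, 188.52, 321.32)
        _, p_gen = strata.strata_rate_analysis(3, 0, 44.23, 158.52, timescale="generations")
        assert round(p_my, 3) == 0.051
        assert round(p_gen, 3) == 0.010

    def test_no_events_p_is_one(self):
        _, p = strata.strata_rate_analysis(0, 0, 10.0, 20.0)
        assert p == 1.0

    def test_tree_based_totals(self):
        tt = strata.TimedTree(
            "((A:10,B:10)N1:5,(C:10,D:10)N2:5)R;",
            tip_ages={t: 5.0 for t in "ABCD"},
            clade_labels={"A": "subtree1", "B": "subtree1", "C": "subtree2", "D": "subtree2"},
        )
        obs, p = strata.strata_rate_analysis(2, 0, tree=tt)
        assert obs.dt1 == pytest.approx(25.0) and obs.dt2 == pytest.approx(25.0)
        assert p == pytest.approx(0.25)
        # generation rescaling with uniform gamma just divides both totals
        obs_g, p_g = strata.strata_rate_analysis(2, 0, tree=tt, timescale="generations")
        assert obs_g.dt1 == pytest.approx(5.0) and p_g == pytest.approx(p)

    def test_unlabeled_tips_rejected(self):
        tt = strata.TimedTree(
            "((A:10,B:10):5,(C:10,D:10):5)R;",
            tip_ages={t: 5.0 for t in "ABCD"},
            clade_labels={"A": "subtree1"},
        )
        with pytest.raises(ValueError, match="unlabeled"):
            strata.strata_rate_analysis(1, 0, tree=tt)

    def test_null_calibration_is_conservative(self):
        reps = sim.simulate_strata_counts(188.52, 321.32, 0.01, n_reps=2000, seed=5)
        rejections = sum(
            strata.conditional_binomial_test(s1, s2, 188.52, 321.32) <= 0.05
            for s1, s2 in reps
        )
        assert rejections / len(reps) <= 0.06
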