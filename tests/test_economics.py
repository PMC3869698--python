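"""Incremental arithmetic, dominance, NMB, PSA, CEAC, CE-plane."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ceatree.cohort import build_view
from ceatree.economics import (
    PSAResult,
    ce_plane,
    ceac,
    incremental_analysis,
    net_monetary_benefit,
    run_psa,
)
from ceatree.fixtures import trees_from_cohort
from ceatree.tree_model import (
    DecisionTree,
    EffectVector,
    HealthState,
    ProbabilitySpec,
    StrategyResult,
    chance,
    resolve_probs,
    rollback,
    terminal,
)


def result(cost, surv28=0.0, surv1y=0.0, mfs=0.0, strategy="arm"):
    return StrategyResult(strategy, cost, EffectVector(surv28, surv1y, mfs))


def psa_from_deltas(dc, de, outcome="surv28"):
    """Hand-built PSA: comparator pinned at zero cost/effect."""
    dc = np.asarray(dc, dtype=float)
    de = np.asarray(de, dtype=float)
    eff = np.zeros((dc.size, 3))
    eff[:, 0] = de
    return PSAResult("vas", "conservative", dc, eff,
                     np.zeros(dc.size), np.zeros((dc.size, 3)))


class TestIncremental:
    def test_published_survival_increments(self):
        """VAS £20,851 / 1.38 survivors vs conservative £9,868 / 0.67:
        increments £10,983 and 0.71; full-precision ICER ~£15,469."""
        inc = incremental_analysis(result(20_851, surv28=1.38),
                                   result(9_868, surv28=0.67), "surv28")
        assert inc.delta_cost == pytest.approx(10_983)
        assert inc.delta_effect == pytest.approx(0.71)
        assert inc.classification == "icer_reported"
        assert inc.icer == pytest.approx(10_983 / 0.71)

    def test_published_morbidity_free_icer(self):
        inc = incremental_analysis(result(20_851, mfs=0.25),
                                   result(9_868, mfs=0.0), "mfs")
        assert inc.icer == pytest.approx(43_932)

    def test_cheaper_and_more_effective_is_dominant(self):
        """The outlier-substitution scenario: VAS cheaper at £9,212 with
        better survival is dominance, not a negative headline ratio."""
        inc = incremental_analysis(result(9_212, surv28=1.38),
                                   result(9_868, surv28=0.67), "surv28")
        assert inc.classification == "intervention_dominant"
        assert inc.icer is None
        assert inc.signed_ratio == pytest.approx((9_212 - 9_868) / 0.71)

    def test_equal_effect_reports_no_ratio(self):
        inc = incremental_analysis(result(10_000, mfs=0.0), result(9_000, mfs=0.0), "mfs")
        assert inc.classification == "equal_effect" and inc.icer is None


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(result(1234.0, surv28=0.9), "surv28", 0.0) == -1234.0

    def test_break_even(self):
        assert net_monetary_benefit(result(20_000, surv28=1.0), "surv28", 20_000) == 0.0

    def test_rejects_negative_wtp(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(result(0.0), "surv28", -1.0)

    @given(st.floats(1.0, 1e5), st.floats(0.05, 1.0), st.floats(0.0, 1e5))
    def test_nmb_difference_vanishes_at_icer(self, dc, de, base_cost):
        """wtp = ICER makes the two arms' NMB equal (algebraic identity)."""
        a = result(base_cost + dc, surv28=min(de + 0.0, 1.0))
        b = result(base_cost, surv28=0.0)
        icer = dc / de
        diff = net_monetary_benefit(a, "surv28", icer) - net_monetary_benefit(b, "surv28", icer)
        assert diff == pytest.approx(0.0, abs=1e-6 * max(1.0, dc))


def fixed_pair():
    def tree(name, p, costs):
        nodes = {
            "r": chance("r", [("a", "t1"), ("b", "t2")],
                        ProbabilitySpec((0, 0), "fixed", p)),
            "t1": terminal("t1", cost=costs[0], state=HealthState.ALIVE_NO_MORBIDITY),
            "t2": terminal("t2", cost=costs[1], state=HealthState.NEONATAL_DEATH),
        }
        return DecisionTree(name, "r", nodes)
    return (tree("vas", (0.5, 0.5), (20_000.0, 10_000.0)),
            tree("conservative", (0.25, 0.75), (8_000.0, 6_000.0)))


class TestPSA:
    def test_seed_reproducibility(self):
        a, b = fixed_pair()
        a.nodes["r"].spec = ProbabilitySpec((8, 8))
        r1 = run_psa(a, b, n_iter=10, seed=4)
        r2 = run_psa(a, b, n_iter=10, seed=4)
        np.testing.assert_array_equal(r1.cost_intervention, r2.cost_intervention)
        np.testing.assert_array_equal(r1.effects_comparator, r2.effects_comparator)

    def test_all_fixed_nodes_reduce_to_base_case(self):
        a, b = fixed_pair()
        psa = run_psa(a, b, n_iter=25, seed=0)
        base = rollback(a, resolve_probs(a))
        np.testing.assert_allclose(psa.cost_intervention, base.expected_cost)
        np.testing.assert_allclose(psa.effects_intervention[:, 0],
                                   base.expected_effects.surv28)

    def test_zero_count_error_names_node(self):
        a, b = fixed_pair()
        a.nodes["r"].spec = ProbabilitySpec((8, 0))
        with pytest.raises(ValueError, match="'r'"):
            run_psa(a, b, n_iter=5, seed=0, regime="mle_centred")

    def test_fixture_psa_means_track_base_case(self, default_cohort):
        """Mean PSA arm costs sit within 2% of the base-case rollback on
        the shipped cohort at 20,000 iterations — the probabilistic
        analysis does not move the base-case picture."""
        trees = trees_from_cohort(build_view(default_cohort, "itt"), regime="mle")
        base = {a: rollback(t, resolve_probs(t)) for a, t in trees.items()}
        psa = run_psa(trees["vas"], trees["conservative"], n_iter=20_000, seed=123)
        assert psa.cost_intervention.mean() == pytest.approx(
            base["vas"].expected_cost, rel=0.02)
        assert psa.cost_comparator.mean() == pytest.approx(
            base["conservative"].expected_cost, rel=0.02)

    def test_scale_equivariance_of_costs(self, default_cohort):
        """Multiplying all terminal costs by k scales dC and the ICER by
        exactly k."""
        trees = trees_from_cohort(build_view(default_cohort, "itt"), regime="mle")
        res = {a: rollback(t, resolve_probs(t)) for a, t in trees.items()}
        inc = incremental_analysis(res["vas"], res["conservative"], "surv28")
        k = 3.5
        for t in trees.values():
            for term in t.terminals():
                term.payoff.cost *= k
        res_k = {a: rollback(t, resolve_probs(t)) for a, t in trees.items()}
        inc_k = incremental_analysis(res_k["vas"], res_k["conservative"], "surv28")
        assert inc_k.delta_cost == pytest.approx(k * inc.delta_cost)
        if inc.classification == "icer_reported":
            assert inc_k.icer == pytest.approx(k * inc.icer)


class TestCEAC:
    def test_hand_built_four_iteration_curve(self):
        """dC/dE pairs (-1,1),(1,1),(3,1),(5,1): at WTP 2 exactly two of
        four iterations have positive incremental NMB."""
        psa = psa_from_deltas([-1, 1, 3, 5], [1, 1, 1, 1])
        curve = ceac(psa, "surv28", [2.0])
        assert curve["p_cost_effective"].iloc[0] == 0.5

    def test_degenerate_psa_is_a_step_at_the_icer(self):
        psa = psa_from_deltas([1000.0] * 8, [0.5] * 8)
        curve = ceac(psa, "surv28", [1000.0, 1999.0, 2001.0, 4000.0])
        assert list(curve["p_cost_effective"]) == [0.0, 0.0, 1.0, 1.0]

    def test_limits_match_delta_sign_fractions(self):
        """p(0) = P(dC < 0); p at a grid end far beyond the ICER equals
        P(dE > 0) (deltas bounded away from zero)."""
        rng = np.random.default_rng(2)
        dc = rng.normal(1000, 800, 500)
        de = np.where(rng.random(500) < 0.8, 1.0, -1.0) * rng.uniform(0.1, 0.5, 500)
        psa = psa_from_deltas(dc, de)
        icer = dc.mean() / de.mean()
        curve = ceac(psa, "surv28", [0.0, 100 * abs(icer)])
        assert curve["p_cost_effective"].iloc[0] == (dc < 0).mean()
        assert abs(curve["p_cost_effective"].iloc[-1] - (de > 0).mean()) <= 1 / 500
        assert curve["p_cost_effective"].between(0, 1).all()

    def test_nmb_difference_changes_sign_once_at_the_icer(self, default_cohort):
        """For a non-dominant base case the incremental NMB crosses zero
        exactly once along an increasing WTP grid, at the ICER."""
        trees = trees_from_cohort(build_view(default_cohort, "itt"), regime="mle")
        res = {a: rollback(t, resolve_probs(t)) for a, t in trees.items()}
        inc = incremental_analysis(res["vas"], res["conservative"], "surv28")
        assert inc.classification == "icer_reported"
        grid = np.linspace(0, 10 * inc.icer, 2001)
        diff = np.array([
            net_monetary_benefit(res["vas"], "surv28", w)
            - net_monetary_benefit(res["conservative"], "surv28", w)
            for w in grid])
        signs = np.sign(diff[np.abs(diff) > 1e-9])
        changes = int((np.diff(signs) != 0).sum())
        assert changes == 1
        crossing = grid[np.argmin(np.abs(diff))]
        assert crossing == pytest.approx(inc.icer, rel=0.01)

    def test_empty_psa_rejected(self):
        psa = psa_from_deltas([], [])
        with pytest.raises(ValueError):
            ceac(psa, "surv28", [0.0, 1.0])


class TestCEPlane:
    def test_degenerate_cloud_sits_north_east(self):
        plane = ce_plane(psa_from_deltas([100.0] * 10, [0.2] * 10), "surv28")
        assert plane.quadrants["NE"] == 10

    def test_sign_flip_symmetry(self):
        dc = np.array([10.0, -10.0, 5.0, -5.0])
        de = np.array([0.1, -0.1, -0.2, 0.2])
        q = ce_plane(psa_from_deltas(dc, de), "surv28").quadrants
        assert q["NE"] == q["SW"] and q["NW"] == q["SE"]

    def test_fixture_majority_north_east(self, default_cohort):
        """On the shipped cohort most PSA points show VAS dearer and
        more effective (upper-right quadrant)."""
        trees = trees_from_cohort(build_view(default_cohort, "itt"), regime="mle")
        psa = run_psa(trees["vas"], trees["conservative"], n_iter=4000, seed=11)
        q = ce_plane(psa, "surv28").quadrants
        assert q["NE"] > psa.iterations / 2
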