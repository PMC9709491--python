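"""Discounting, utilities, accrual and the cost-effectiveness frontier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dupsim
from dupsim.economics import (
    accrue,
    cycle_utility,
    discount_factor,
    incremental_analysis,
)
from dupsim.engine import simulate_cohort, simulate_patient
from dupsim.states import ADALIMUMAB_REPEAT, STANDARD_CARE, State


class TestDiscounting:
    def test_trial_period_undiscounted(self, params):
        assert discount_factor(0.0, params) == 1.0
        assert discount_factor(1.5, params) == 1.0

    def test_closed_form_beyond_trial(self, params):
        assert discount_factor(3.5, params) == pytest.approx(1.035**-2)
        assert discount_factor(3.5, params) == pytest.approx(0.93351, abs=1e-5)

    def test_zero_rate(self, params):
        p = params.replace(discount_rate=0.0)
        assert np.all(discount_factor(np.array([0.0, 10.0, 55.0]), p) == 1.0)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            discount_factor(-0.1, params)


class TestUtilities:
    def test_quiescence_gain_is_exact(self, params):
        u_prog = cycle_utility(State.EARLY_PROGRESSIVE, 0.8, params)
        u_quie = cycle_utility(State.EARLY_QUIESCENT, 0.8, params)
        assert u_quie - u_prog == pytest.approx(0.0395)

    def test_capped_at_one(self, params):
        p = params.replace(qaly_reg_constant=0.9)
        assert cycle_utility(State.EARLY_QUIESCENT, 1.0, p) == 1.0

    def test_zero_decrement_equals_progressive(self, params):
        p = params.replace(
            utility_decrement_late_untreated=0.0,
            utility_decrement_post_pnf_success=0.0,
            utility_decrement_post_pnf_failed=0.0,
            utility_decrement_post_fasciectomy=0.0,
            utility_decrement_post_dermofasciectomy=0.0,
        )
        u_prog = cycle_utility(State.EARLY_PROGRESSIVE, 0.8, p)
        for s in (State.LATE_UNTREATED, State.LATE_POST_FASCIECTOMY):
            assert cycle_utility(s, 0.8, p) == pytest.approx(u_prog)

    def test_dead_state_zero(self, params):
        assert cycle_utility(State.DEAD, 0.8, params) == 0.0


class TestAccrual:
    def test_accrue_matches_engine_accumulation(self, params, patient):
        """Recomputing discounted totals from the per-cycle record reproduces
        the engine's internal accumulation."""
        import pandas as pd

        tr = simulate_patient(patient, STANDARD_CARE, "progressive", params, np.random.default_rng(6))
        cohort = pd.DataFrame(
            {
                "id": [patient.id], "age": [patient.age], "sex": [patient.sex],
                "baseline_utility": [patient.baseline_utility],
                "baseline_fd": [patient.baseline_fd], "ectopic": [patient.ectopic],
            }
        )
        res = simulate_cohort(
            cohort, STANDARD_CARE, np.array([0]), params, rng=np.random.default_rng(6)
        )
        cost, qalys, _ = accrue(tr, params)
        assert cost == pytest.approx(res.summary["cost_model"].iloc[0])
        assert qalys == pytest.approx(res.summary["qalys_model"].iloc[0])

    def test_retreatment_course_costs_discounted_closed_form(self, params, patient):
        """With mortality switched off, the retreatment strategy applies one
        course at trial end plus 4 x GBP 475 at t = 4.5, 7.5, ... discounted
        from 18 months (first retreatment factor 1.035^-3)."""
        p = params.replace(gompertz_rate=1e-30)
        tr = simulate_patient(patient, ADALIMUMAB_REPEAT, "quiescent", p, np.random.default_rng(0))
        cost, _, events = accrue(tr, p)
        react_times = np.arange(4.5, p.horizon, 3.0)
        expected = sum(p.course_cost * 1.035 ** -(t - 1.5) for t in react_times)
        assert cost == pytest.approx(expected)
        assert events["course_started"] == len(react_times)

    def test_standard_care_without_surgery_costs_nothing(self, params, patient):
        p = params.replace(p_elect_surgery=0.0)
        tr = simulate_patient(patient, STANDARD_CARE, "progressive", p, np.random.default_rng(1))
        cost, _, _ = accrue(tr, p)
        assert cost == 0.0

    def test_zero_utilities_zero_qalys(self, params, patient):
        p = params.replace(
            qaly_reg_constant=0.0, qaly_reg_baseline_utility_coef=0.0,
            qaly_gain_quiescence=0.0,
            utility_decrement_late_untreated=0.0,
            utility_decrement_post_pnf_success=0.0,
            utility_decrement_post_pnf_failed=0.0,
            utility_decrement_post_fasciectomy=0.0,
            utility_decrement_post_dermofasciectomy=0.0,
        )
        tr = simulate_patient(patient, STANDARD_CARE, "quiescent", p, np.random.default_rng(2))
        _, qalys, _ = accrue(tr, p)
        assert qalys == 0.0

    def test_discounted_qalys_bounded_by_life_years(self, params, cohort69):
        per = dupsim.evaluate_strategies(cohort69, params, n_reps=5, seed=3)
        for df in per.values():
            assert (df["qalys_model"] <= df["life_years"] + 1e-9).all()


def _brute_force_flags(strategies):
    """Independent frontier oracle: a strategy is on the frontier iff it
    uniquely maximizes net benefit for some willingness-to-pay."""
    names = list(strategies)
    costs = np.array([strategies[n][0] for n in names])
    qalys = np.array([strategies[n][1] for n in names])
    dominated = {}
    for i, n in enumerate(names):
        dominated[n] = any(
            j != i
            and costs[j] <= costs[i]
            and qalys[j] >= qalys[i]
            and (costs[j] < costs[i] or qalys[j] > qalys[i])
            for j in range(len(names))
        )
    # candidate willingness-to-pay values: midpoints between every pairwise
    # ICER breakpoint (where the argmax can change), plus the extremes
    breaks = sorted(
        {
            (costs[i] - costs[j]) / (qalys[i] - qalys[j])
            for i in range(len(names))
            for j in range(len(names))
            if qalys[i] != qalys[j] and (costs[i] - costs[j]) / (qalys[i] - qalys[j]) > 0
        }
    )
    grid = [0.0, *breaks, (breaks[-1] * 2 + 1 if breaks else 1.0)]
    candidates = [0.0] + [(a + b) / 2 for a, b in zip(grid[:-1], grid[1:])] + [grid[-1] + 1]
    wins = {n: False for n in names}
    for lam in candidates:
        nb = lam * qalys - costs
        best = np.flatnonzero(nb >= nb.max() - 1e-9 * max(1.0, abs(nb.max())))
        if len(best) == 1:
            wins[names[best[0]]] = True
    extended = {n: (not dominated[n]) and (not wins[n]) for n in names}
    return dominated, extended


class TestIncrementalAnalysis:
    def test_strictly_dominated_toy(self):
        table = incremental_analysis({"a": (0.0, 10.0), "b": (100.0, 10.0)})
        assert not table.set_index("strategy").loc["a", "dominated"]
        assert table.set_index("strategy").loc["b", "dominated"]

    def test_extended_dominance_toy(self):
        table = incremental_analysis({"a": (0.0, 0.0), "b": (10.0, 1.0), "c": (12.0, 3.0)})
        t = table.set_index("strategy")
        assert t.loc["b", "extended_dominated"] and not t.loc["b", "dominated"]
        assert t.loc["c", "icer_frontier"] == pytest.approx(4.0)

    def test_undefined_icer_not_divided(self):
        t = incremental_analysis({"standard_care": (0.0, 1.0), "b": (5.0, 1.0)})
        assert np.isnan(t.set_index("strategy").loc["b", "icer_vs_reference"])

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError):
            incremental_analysis({"a": (0.0, 1.0)})

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        strategies = {
            f"s{i}": (float(rng.uniform(0, 1000)), float(rng.uniform(0, 10))) for i in range(k)
        }
        table = incremental_analysis(strategies).set_index("strategy")
        dom_o, ext_o = _brute_force_flags(strategies)
        for name in strategies:
            assert bool(table.loc[name, "dominated"]) == dom_o[name], name
            assert bool(table.loc[name, "extended_dominated"]) == ext_o[name], name
        icers = table["icer_frontier"].dropna().to_numpy()
        assert np.all(np.diff(icers) > 0)  # frontier ICERs strictly increasing

    def test_removing_dominated_strategy_preserves_frontier(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            strategies = {
                f"s{i}": (float(rng.uniform(0, 100)), float(rng.uniform(0, 10))) for i in range(5)
            }
            table = incremental_analysis(strategies).set_index("strategy")
            dominated = table.index[table["dominated"]].tolist()
            if not dominated:
                continue
            reduced = {k: v for k, v in strategies.items() if k != dominated[0]}
            t2 = incremental_analysis(reduced).set_index("strategy")
            front1 = table[~table["dominated"] & ~table["extended_dominated"]].index
            front2 = t2[~t2["dominated"] & ~t2["extended_dominated"]].index
            assert set(front1) == set(front2)


class TestNullEffect:
    def test_equal_arms_and_free_course_give_zero_incrementals(self, params, cohort69):
        """When adalimumab confers placebo outcome probabilities and the
        course is free, one course vs standard care differs by nothing under
        common random numbers."""
        p = params.replace(
            p_late_ada=params.p_late_placebo,
            p_quiescent_ada=params.p_quiescent_placebo,
            cost_per_dose=0.0,
            trial_background_cost=0.0,
        )
        per = dupsim.evaluate_strategies(cohort69, p, n_reps=5, seed=4)
        sc, once = per["standard_care"], per["adalimumab_once"]
        np.testing.assert_allclose(once["cost_lifetime"], sc["cost_lifetime"])
        np.testing.assert_allclose(once["qalys_lifetime"], sc["qalys_lifetime"])
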