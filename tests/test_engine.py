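"""Disease-course engine: flexion walk, surgical pathway, mortality, state machine."""

import numpy as np
import pandas as pd
import pytest

import dupsim
from dupsim.cohort import OUTCOME_LATE, OUTCOME_PROGRESSIVE, OUTCOME_QUIESCENT
from dupsim.engine import (
    SurgicalHistory,
    cycle_mortality_prob,
    draw_cycle_randoms,
    expected_fd_change_18m,
    next_surgical_event,
    progress_flexion,
    read_trajectories,
    simulate_cohort,
    simulate_patient,
    write_trajectories,
)
from dupsim.states import (
    ADALIMUMAB_REPEAT,
    DEFAULT_STRATEGIES,
    STANDARD_CARE,
    State,
)

P, Q = State.EARLY_PROGRESSIVE, State.EARLY_QUIESCENT
LU, PS, PF = State.LATE_UNTREATED, State.LATE_POST_PNF_SUCCESS, State.LATE_POST_PNF_FAILED
FA, DF, DE = State.LATE_POST_FASCIECTOMY, State.LATE_POST_DERMOFASCIECTOMY, State.DEAD

LEGAL_TRANSITIONS = {
    (P, P), (P, LU), (P, DE),
    (Q, Q), (Q, P), (Q, DE),
    (LU, LU), (LU, PS), (LU, PF), (LU, FA), (LU, DF), (LU, DE),
    (PS, PS), (PS, LU), (PS, DE),
    (PF, PF), (PF, FA), (PF, DE),
    (FA, FA), (FA, LU), (FA, DE),
    (DF, DF), (DF, LU), (DF, DE),
    (DE, DE),
}


class TestFlexionWalk:
    def test_deterministic_increment_without_noise(self, params, rng):
        p = params.replace(fd_change_rmse=0.0)
        assert progress_flexion(10.0, False, p, rng) == pytest.approx(10.0 + 0.8631 / 3)
        assert progress_flexion(10.0, True, p, rng) == pytest.approx(10.0 + 9.3820 / 3, abs=1e-4)

    def test_floor_at_zero(self, params, rng):
        p = params.replace(fd_change_constant=-1e6, fd_change_rmse=0.0)
        assert progress_flexion(0.0, False, p, rng) == 0.0
        with pytest.raises(ValueError):
            progress_flexion(-1.0, False, params, rng)

    def test_three_cycles_reproduce_18_month_regression(self, params, rng):
        """Cumulative 18-month drift for ectopic patients matches the published
        regression prediction (well away from the floor at 0 degrees)."""
        n = 300_000
        fd = np.full(n, 1e6)
        start = fd.copy()
        for _ in range(3):
            fd = progress_flexion(fd, np.ones(n, bool), params, rng)
        mc_se = params.fd_change_rmse / np.sqrt(n)
        assert abs((fd - start).mean() - 9.3821) < 3 * mc_se

    def test_expected_change_prediction(self, params):
        assert expected_fd_change_18m(params, ectopic=False) == pytest.approx(0.8631)
        assert expected_fd_change_18m(params, ectopic=True) == pytest.approx(9.3821, abs=1.5e-4)


class TestSurgicalPathway:
    def test_pnf_repeated_only_after_success(self):
        h = SurgicalHistory(n_pnf=1, last_pnf_success=True)
        assert next_surgical_event(h, None) == "pnf"

    def test_three_pnfs_exhausted_then_fasciectomy(self):
        h = SurgicalHistory(n_pnf=3, last_pnf_success=True)
        assert next_surgical_event(h, None) == "limited_fasciectomy"

    def test_failed_pnf_never_repeated(self):
        h = SurgicalHistory(n_pnf=1, pnf_failed=True)
        assert next_surgical_event(h, None) == "limited_fasciectomy"

    def test_sequence_ends_in_supportive_care(self):
        h = SurgicalHistory(n_pnf=3, pnf_failed=True, had_fasciectomy=True, had_dermofasciectomy=True)
        assert next_surgical_event(h, None) is None
        h2 = SurgicalHistory(n_pnf=3, had_fasciectomy=True)
        assert next_surgical_event(h2, None) == "dermofasciectomy"

    def test_history_bounds(self):
        with pytest.raises(ValueError):
            SurgicalHistory(n_pnf=4)


class TestMortality:
    @staticmethod
    def _life_table_params(params, hr):
        table = pd.DataFrame(
            {
                "age": list(range(0, 101)) * 2,
                "sex": ["male"] * 101 + ["female"] * 101,
                "hazard": [0.02] * 202,
            }
        )
        return params.replace(dd_hazard_ratio=hr, life_table=table)

    def test_unit_hazard_ratio_matches_life_table(self, params):
        p = self._life_table_params(params, hr=1.0)
        q = cycle_mortality_prob(70.0, np.array(["male"]), p)
        assert q[0] == pytest.approx(1.0 - np.exp(-0.02 * 0.5))

    def test_doubled_hazard_on_survival_scale(self, params):
        p1 = self._life_table_params(params, hr=1.0)
        p2 = self._life_table_params(params, hr=2.0)
        q1 = cycle_mortality_prob(70.0, np.array(["male"]), p1)[0]
        q2 = cycle_mortality_prob(70.0, np.array(["male"]), p2)[0]
        assert 1.0 - q2 == pytest.approx((1.0 - q1) ** 2)

    def test_beyond_table_maximum_is_certain_death(self, params):
        p = self._life_table_params(params, hr=1.0)
        assert cycle_mortality_prob(105.0, np.array(["female"]), p)[0] == 1.0

    def test_strategy_has_no_effect_on_survival(self, params, cohort69):
        per = dupsim.evaluate_strategies(cohort69, params, n_reps=3, seed=8)
        ref = per["standard_care"]["life_years"]
        for name, df in per.items():
            np.testing.assert_array_equal(df["life_years"].to_numpy(), ref.to_numpy())


class TestTrajectories:
    def test_late_assignment_starts_untreated_late(self, params, patient, rng):
        tr = simulate_patient(patient, STANDARD_CARE, "late_stage", params, rng)
        assert tr.frame["state"].iloc[0] == "LATE_UNTREATED"
        assert tr.entered_late

    def test_horizon_respected(self, params, patient):
        for seed in range(5):
            tr = simulate_patient(
                patient, STANDARD_CARE, "progressive", params, np.random.default_rng(seed)
            )
            assert tr.frame["time"].max() <= params.horizon - params.cycle_length + 1e-9
            assert np.all(np.diff(tr.frame["time"]) == pytest.approx(params.cycle_length))

    def test_repeat_strategy_course_count_closed_form(self, params, patient):
        """Under retreatment, an initially quiescent patient never reaches
        late-stage disease and receives 1 + floor((death - 1.5)/3) courses."""
        qd = params.quiescence_duration
        for seed in range(40):
            tr = simulate_patient(
                patient, ADALIMUMAB_REPEAT, "quiescent", params, np.random.default_rng(seed)
            )
            assert not tr.entered_late
            death = tr.death_time if np.isfinite(tr.death_time) else params.horizon
            react_times = np.arange(params.trial_period + qd, params.horizon, qd)
            expected = 1 + int(np.sum(react_times < death - 1e-9))
            assert tr.courses == expected

    def test_quiescent_cycles_never_change_flexion(self, params, patient):
        tr = simulate_patient(
            patient, ADALIMUMAB_REPEAT, "quiescent", params, np.random.default_rng(3)
        )
        quiescent = tr.frame["state"] == "EARLY_QUIESCENT"
        assert tr.frame.loc[quiescent, "fd"].nunique() == 1

    def test_trajectory_csv_round_trip(self, params, patient, tmp_path, rng):
        tr = simulate_patient(patient, STANDARD_CARE, "progressive", params, rng)
        path = tmp_path / "traj.csv"
        write_trajectories([tr], path)
        back = read_trajectories(path)
        assert len(back) == len(tr.frame)
        assert (back["strategy"] == "standard_care").all()


def _audit_run(params, cohort69, n_total=3500, seed=77):
    big = pd.concat([cohort69] * (n_total // len(cohort69) + 1), ignore_index=True).iloc[:n_total]
    rng = np.random.default_rng(seed)
    u = rng.random(n_total)
    randoms = draw_cycle_randoms(rng, n_total, params.n_cycles)
    out = []
    for s in DEFAULT_STRATEGIES:
        p_late, p_q = (
            (params.p_late_ada, params.p_quiescent_ada)
            if s.initial_course
            else (params.p_late_placebo, params.p_quiescent_placebo)
        )
        codes = np.full(n_total, OUTCOME_PROGRESSIVE)
        codes[u < p_late] = OUTCOME_LATE
        codes[u >= 1 - p_q] = OUTCOME_QUIESCENT
        out.append(simulate_cohort(big, s, codes, params, randoms=randoms, record=True))
    return out


class TestStateMachine:
    def test_transition_legality_and_surgery_caps(self, params, cohort69):
        """Exhaustive audit over >10^4 trajectories: every observed transition
        is a legal edge of the state diagram and no trajectory exceeds the
        surgical caps (3 PNF, 1 limited fasciectomy, 1 dermofasciectomy)."""
        results = _audit_run(params, cohort69)
        for res in results:
            st = res.states
            pairs = set(zip(st[:, :-1].ravel().tolist(), st[:, 1:].ravel().tolist()))
            illegal = {(State(a).name, State(b).name) for a, b in pairs} - {
                (State(a).name, State(b).name) for a, b in LEGAL_TRANSITIONS
            }
            assert not illegal
            ev = res.events
            assert ((ev & 2) > 0).sum(axis=1).max() <= 3  # PNF
            assert ((ev & 4) > 0).sum(axis=1).max() <= 1  # limited fasciectomy
            assert ((ev & 8) > 0).sum(axis=1).max() <= 1  # dermofasciectomy
            # late-stage entry is absorbing with respect to early states
            late = np.isin(st, [LU, PS, PF, FA, DF])
            early_after_late = late[:, :-1] & np.isin(st[:, 1:], [P, Q])
            assert not early_after_late.any()

    def test_bit_reproducible(self, params, cohort69):
        a = dupsim.evaluate_strategies(cohort69, params, n_reps=2, seed=5)
        b = dupsim.evaluate_strategies(cohort69, params, n_reps=2, seed=5)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_quiescence_duration_monotone_time_to_late(self, params, patient):
        """With common random numbers, lengthening quiescence never brings
        forward a quiescent standard-care patient's late-stage onset."""
        def onset(qd, seed):
            p = params.replace(quiescence_duration=qd)
            tr = simulate_patient(patient, STANDARD_CARE, "quiescent", p, np.random.default_rng(seed))
            late = tr.frame["state"].str.startswith("LATE")
            return tr.frame.loc[late, "time"].iloc[0] if late.any() else np.inf

        for seed in range(30):
            onsets = [onset(qd, seed) for qd in (1.5, 3.0, 4.5)]
            assert onsets == sorted(onsets)
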