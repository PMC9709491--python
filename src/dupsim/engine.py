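"""Lifetime disease-course simulation in six-month cycles.

Each patient's trajectory starts at the end of the 18-month trial
(``t = 1.5`` years from randomization) in the 18-month outcome state assigned
for the strategy, and runs cycle by cycle until death or the 55-year horizon:

* **quiescent** patients hold their flexion deformity fixed until quiescence
  ends (``quiescence_duration`` years after trial end); they then either
  become progressive (standard care / one course) or, under the retreatment
  strategy, receive a further course in that same cycle and remain quiescent
  indefinitely;
* **progressive** patients follow a Gaussian random walk in flexion
  deformity, floored at 0 deg; the published 18-month regression is scaled to
  6-month increments as mean/3 and SD/sqrt(3), so three increments reproduce
  the published 18-month mean and residual RMSE.  Crossing the late-stage
  threshold (>30 deg) is permanent;
* **late-stage** patients may elect surgery: up to three percutaneous needle
  fasciotomies (PNF, repeated only after an initially successful procedure
  relapses), then at most one limited fasciectomy, then at most one
  dermofasciectomy; afterwards, best supportive care;
* mortality (life-table hazard times a disease hazard ratio) applies in every
  state and is independent of strategy.

A patient alive at cycle start accrues the full cycle's cost and utility;
survival to the next cycle is then tested (no half-cycle correction).

Random-number discipline: all per-cycle uniforms and normals are drawn
up-front in fixed shapes, so identical seeds give bit-identical trajectories
and the same arrays can be shared across strategies (common random numbers).
Flexion shocks are indexed by *progression age* -- cycles since the walk
started -- so lengthening quiescence shifts, and never shortens, the time to
late-stage disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import economics
from .cohort import OUTCOME_LATE, OUTCOME_PROGRESSIVE, OUTCOME_QUIESCENT, Patient
from .params import ModelParameters
from .states import (
    ADALIMUMAB_ONCE,
    ADALIMUMAB_REPEAT,
    STANDARD_CARE,
    State,
    StrategySpec,
    SURGERY_ELIGIBLE_STATES,
)

__all__ = [
    "SurgicalHistory",
    "Trajectory",
    "SimulationResult",
    "simulate_cohort",
    "simulate_patient",
    "progress_flexion",
    "next_surgical_event",
    "cycle_mortality_prob",
    "expected_fd_change_18m",
    "draw_cycle_randoms",
    "replicate_cohort",
    "write_trajectories",
    "read_trajectories",
]

_MAX_PNF = 3

# event codes used in the vectorized record
_EV_NONE, _EV_COURSE, _EV_PNF, _EV_LF, _EV_DF, _EV_DEATH = 0, 1, 2, 4, 8, 16
_EV_LABELS = {
    _EV_COURSE: "course_started",
    _EV_PNF: "pnf",
    _EV_LF: "limited_fasciectomy",
    _EV_DF: "dermofasciectomy",
    _EV_DEATH: "death",
}


@dataclass
class SurgicalHistory:
    """Running record of a patient's late-stage procedures."""

    n_pnf: int = 0
    last_pnf_success: bool = False
    pnf_failed: bool = False
    had_fasciectomy: bool = False
    had_dermofasciectomy: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_pnf <= _MAX_PNF:
            raise ValueError(f"n_pnf must lie in [0, {_MAX_PNF}]")


def next_surgical_event(history: SurgicalHistory, params: ModelParameters) -> str | None:
    """The next procedure offered to an eligible late-stage patient.

    PNF while fewer than three have been performed and none has failed;
    otherwise limited fasciectomy (once), then dermofasciectomy (once), then
    best supportive care (``None``).  Whether the patient *elects* surgery in
    a given cycle is governed separately by ``late_stage.p_elect_surgery``.
    """
    if history.n_pnf < _MAX_PNF and not history.pnf_failed:
        return "pnf"
    if not history.had_fasciectomy:
        return "limited_fasciectomy"
    if not history.had_dermofasciectomy:
        return "dermofasciectomy"
    return None


def progress_flexion(
    fd, ectopic, params: ModelParameters, rng: np.random.Generator
):
    """One 6-month flexion-deformity increment, floored at 0 degrees.

    The increment is Normal with mean ``(constant + ectopic_coef x ectopic)/3``
    and SD ``rmse / sqrt(3)``, so the sum of three cycles reproduces the
    published 18-month regression mean and residual RMSE.
    """
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("flexion deformity must be non-negative")
    ect = np.asarray(ectopic, dtype=bool)
    mu = (params.fd_change_constant + params.fd_change_ectopic_coef * ect) / 3.0
    sd = params.fd_change_rmse / np.sqrt(3.0)
    delta = rng.normal(mu, sd, size=fd.shape) if fd.shape else rng.normal(mu, sd)
    out = np.maximum(fd + delta, 0.0)
    return out if fd.shape else float(out)


def expected_fd_change_18m(params: ModelParameters, ectopic: bool) -> float:
    """Model-predicted mean 18-month flexion-deformity change, untreated.

    The regression prediction: the constant, plus the ectopic-disease
    coefficient for patients with ectopic fibrotic disease.
    """
    return params.fd_change_constant + (params.fd_change_ectopic_coef if ectopic else 0.0)


def cycle_mortality_prob(age, sex, params: ModelParameters):
    """Per-cycle death probability at attained ``age``.

    ``1 - exp(-HR * h(age, sex) * cycle_length)`` with ``h`` the life-table
    annual hazard; independent of disease state and treatment strategy.
    """
    h = params.mortality.annual_hazard(age, sex)
    return 1.0 - np.exp(-params.mortality.dd_hazard_ratio * h * params.cycle_length)


def draw_cycle_randoms(rng: np.random.Generator, n: int, n_cycles: int) -> dict[str, np.ndarray]:
    """Pre-draw every random stream the engine consumes, in a fixed order.

    Sharing the returned dict across strategies implements common random
    numbers; drawing everything up-front keeps streams aligned regardless of
    which branches a strategy takes.
    """
    return {
        "z_init": rng.standard_normal(n),
        "z_fd": rng.standard_normal((n, n_cycles)),
        "u_elect": rng.random((n, n_cycles)),
        "u_success": rng.random((n, n_cycles)),
        "u_relapse": rng.random((n, n_cycles)),
        "u_death": rng.random((n, n_cycles)),
    }


def replicate_cohort(cohort: pd.DataFrame, n_reps: int) -> pd.DataFrame:
    """Stack ``n_reps`` copies of the cohort (one row per simulated individual)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = pd.concat([cohort] * n_reps, ignore_index=True)
    out["rep"] = np.repeat(np.arange(n_reps), len(cohort))
    return out


@dataclass
class SimulationResult:
    """Vectorized simulation output for one strategy.

    ``summary`` has one row per simulated individual: model-period discounted
    cost and QALYs, life-years, time in early states, time free of late-stage
    disease (all measured from trial end), courses, operations and late-stage
    entry.  When recorded, ``states``/``fd``/``costs``/``utilities``/``events``
    are (n, n_cycles) matrices and ``times`` the cycle-start times.
    """

    strategy: str
    summary: pd.DataFrame
    times: np.ndarray
    states: np.ndarray | None = None
    fd: np.ndarray | None = None
    costs: np.ndarray | None = None
    utilities: np.ndarray | None = None
    events: np.ndarray | None = None


def simulate_cohort(
    cohort: pd.DataFrame,
    strategy: StrategySpec,
    outcomes: np.ndarray,
    params: ModelParameters,
    rng: np.random.Generator | None = None,
    randoms: Mapping[str, np.ndarray] | None = None,
    record: bool = False,
) -> SimulationResult:
    """Simulate every cohort row from trial end to death or horizon.

    ``outcomes`` holds the 18-month outcome codes already assigned for this
    strategy.  Pass ``randoms`` (from :func:`draw_cycle_randoms`) to share
    random streams across strategies; otherwise they are drawn from ``rng``.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    outcomes = np.asarray(outcomes)
    if outcomes.shape != (n,):
        raise ValueError("outcomes must hold one category per cohort row")
    C = params.n_cycles
    if randoms is None:
        if rng is None:
            raise ValueError("provide either rng or randoms")
        randoms = draw_cycle_randoms(rng, n, C)

    ls = params.late_stage
    thr = params.late_stage_threshold
    dt = params.cycle_length
    qd = params.quiescence_duration
    course_cost = params.course_cost

    age0 = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=object)
    bl_util = cohort["baseline_utility"].to_numpy(dtype=float)
    ectopic = cohort["ectopic"].to_numpy(dtype=bool)

    # state at trial end ----------------------------------------------------
    state = np.empty(n, dtype=np.int64)
    state[outcomes == OUTCOME_PROGRESSIVE] = State.EARLY_PROGRESSIVE
    state[outcomes == OUTCOME_QUIESCENT] = State.EARLY_QUIESCENT
    state[outcomes == OUTCOME_LATE] = State.LATE_UNTREATED

    # flexion deformity at trial end: progressive patients advance by one
    # 18-month regression draw, truncated into [0, threshold] (they are, by
    # assignment, not yet late-stage); quiescent patients keep baseline
    fd = cohort["baseline_fd"].to_numpy(dtype=float).copy()
    mu18 = params.fd_change_constant + params.fd_change_ectopic_coef * ectopic
    init_change = mu18 + params.fd_change_rmse * randoms["z_init"]
    prog0 = outcomes == OUTCOME_PROGRESSIVE
    fd[prog0] = np.clip(fd[prog0] + init_change[prog0], 0.0, thr)
    fd[outcomes == OUTCOME_LATE] = thr + 10.0

    quiesc_end = np.where(state == State.EARLY_QUIESCENT, params.trial_period + qd, np.inf)

    n_pnf = np.zeros(n, dtype=np.int64)
    pnf_failed = np.zeros(n, dtype=bool)
    had_lf = np.zeros(n, dtype=bool)
    had_df = np.zeros(n, dtype=bool)
    prog_age = np.zeros(n, dtype=np.int64)  # cycles since the flexion walk started

    alive = np.ones(n, dtype=bool)
    death_time = np.full(n, np.nan)
    courses = np.full(n, 1 if strategy.initial_course else 0, dtype=np.int64)
    ops = np.zeros(n, dtype=np.int64)
    cost_disc = np.zeros(n)
    qaly_disc = np.zeros(n)
    life_years = np.zeros(n)
    t_early = np.zeros(n)
    t_free_late = np.zeros(n)
    entered_late = outcomes == OUTCOME_LATE

    mu_cycle = mu18 / 3.0
    sd_cycle = params.fd_change_rmse / np.sqrt(3.0)
    dec = economics._decrement_lookup(params)
    base_u = params.qaly_reg_constant + params.qaly_reg_baseline_utility_coef * bl_util

    times = params.trial_period + dt * np.arange(C)
    if record:
        rec_state = np.full((n, C), State.DEAD, dtype=np.int8)
        rec_fd = np.zeros((n, C))
        rec_cost = np.zeros((n, C))
        rec_util = np.zeros((n, C))
        rec_event = np.zeros((n, C), dtype=np.int16)

    idx = np.arange(n)
    for k in range(C):
        t = times[k]
        dfac = economics.discount_factor(float(t), params)
        a = alive
        cycle_cost = np.zeros(n)
        event = np.zeros(n, dtype=np.int16)

        # quiescence ends: retreat (same cycle) or become progressive
        react = a & (state == State.EARLY_QUIESCENT) & (t >= quiesc_end - 1e-9)
        if strategy.retreat_on_reactivation:
            courses[react] += 1
            cycle_cost[react] += course_cost
            quiesc_end[react] += qd
            event[react] |= _EV_COURSE
        else:
            state[react] = State.EARLY_PROGRESSIVE

        # accrual for the cycle ---------------------------------------------
        u = base_u + params.qaly_gain_quiescence * (state == State.EARLY_QUIESCENT) - dec[state]
        u = np.minimum(u, 1.0)
        early = a & (state <= State.EARLY_QUIESCENT)
        not_late = a & ~np.isin(state, _LATE_CODES)
        life_years[a] += dt
        t_early[early] += dt
        # time free of late-stage disease is an effectiveness measure and is
        # discounted like QALYs; early-stage occupancy stays undiscounted
        t_free_late[not_late] += dt * dfac

        # surgery election ---------------------------------------------------
        elig = a & ((state == State.LATE_UNTREATED) | (state == State.LATE_POST_PNF_FAILED))
        offer_pnf = (n_pnf < _MAX_PNF) & ~pnf_failed
        offer_lf = ~offer_pnf & ~had_lf
        offer_df = ~offer_pnf & had_lf & ~had_df
        elect = elig & (offer_pnf | offer_lf | offer_df) & (randoms["u_elect"][:, k] < ls.p_elect_surgery)
        do_pnf = elect & offer_pnf
        do_lf = elect & offer_lf
        do_df = elect & offer_df
        cycle_cost[do_pnf] += ls.cost_pnf + ls.cost_surgery_followup
        cycle_cost[do_lf] += ls.cost_limited_fasciectomy + ls.cost_surgery_followup
        cycle_cost[do_df] += ls.cost_dermofasciectomy + ls.cost_surgery_followup
        ops[elect] += 1
        event[do_pnf] |= _EV_PNF
        event[do_lf] |= _EV_LF
        event[do_df] |= _EV_DF

        cost_disc[a] += cycle_cost[a] * dfac
        qaly_disc[a] += u[a] * dt * dfac

        if record:
            rec_state[a, k] = state[a]
            rec_fd[:, k] = fd
            rec_cost[a, k] = cycle_cost[a]
            rec_util[a, k] = u[a]

        # transitions taking effect next cycle -------------------------------
        new_state = state.copy()
        succ = do_pnf & (randoms["u_success"][:, k] < ls.p_pnf_success)
        new_state[succ] = State.LATE_POST_PNF_SUCCESS
        fail = do_pnf & ~succ
        new_state[fail] = State.LATE_POST_PNF_FAILED
        n_pnf[do_pnf] += 1
        pnf_failed[fail] = True
        new_state[do_lf] = State.LATE_POST_FASCIECTOMY
        had_lf[do_lf] = True
        new_state[do_df] = State.LATE_POST_DERMOFASCIECTOMY
        had_df[do_df] = True

        p_rel = np.zeros(n)
        p_rel[state == State.LATE_POST_PNF_SUCCESS] = ls.p_relapse_pnf
        p_rel[state == State.LATE_POST_FASCIECTOMY] = ls.p_relapse_fasciectomy
        p_rel[state == State.LATE_POST_DERMOFASCIECTOMY] = ls.p_relapse_dermofasciectomy
        relapse = a & (p_rel > 0) & (randoms["u_relapse"][:, k] < p_rel)
        new_state[relapse] = State.LATE_UNTREATED

        prog = a & (state == State.EARLY_PROGRESSIVE)
        if prog.any():
            z = randoms["z_fd"][idx[prog], np.minimum(prog_age[prog], C - 1)]
            fd[prog] = np.maximum(fd[prog] + mu_cycle[prog] + sd_cycle * z, 0.0)
            prog_age[prog] += 1
            to_late = prog & (fd > thr)
            new_state[to_late] = State.LATE_UNTREATED
            entered_late |= to_late

        q_death = cycle_mortality_prob(age0 + t, sex, params)
        die = a & (randoms["u_death"][:, k] < q_death)
        new_state[die] = State.DEAD
        death_time[die] = t + dt
        if record:
            rec_event[:, k] = event
            rec_event[die, k] |= _EV_DEATH
        alive = a & ~die
        state = new_state

    summary = pd.DataFrame(
        {
            "patient_id": cohort["id"].to_numpy(),
            "cost_model": cost_disc,
            "qalys_model": qaly_disc,
            "life_years": life_years,
            "years_early": t_early,
            "years_free_late": t_free_late,
            "courses": courses,
            "operations": ops,
            "entered_late": entered_late,
            "death_time": death_time,
        }
    )
    if "rep" in cohort.columns:
        summary["rep"] = cohort["rep"].to_numpy()
    res = SimulationResult(strategy=strategy.name, summary=summary, times=times)
    if record:
        res.states, res.fd, res.costs, res.utilities, res.events = (
            rec_state, rec_fd, rec_cost, rec_util, rec_event,
        )
    return res


_LATE_CODES = np.array(
    [
        State.LATE_UNTREATED,
        State.LATE_POST_PNF_SUCCESS,
        State.LATE_POST_PNF_FAILED,
        State.LATE_POST_FASCIECTOMY,
        State.LATE_POST_DERMOFASCIECTOMY,
    ],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# single-patient interface
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """One simulated lifetime, cycle by cycle.

    ``frame`` columns: cycle, time (years from randomization), state name,
    flexion deformity, undiscounted cycle cost, annualized cycle utility,
    event string.  Aggregates (courses, operations, death time) are exposed
    as attributes.
    """

    patient_id: int
    strategy: str
    frame: pd.DataFrame
    courses: int
    operations: int
    death_time: float
    entered_late: bool


def _event_string(code: int) -> str:
    return "+".join(label for bit, label in _EV_LABELS.items() if code & bit)


def simulate_patient(
    patient: Patient,
    strategy: StrategySpec,
    outcome: int | str,
    params: ModelParameters,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one patient's lifetime under a strategy, with a full record.

    ``outcome`` is the patient's 18-month outcome for this strategy (code or
    label).  A thin wrapper over the vectorized engine with ``n = 1``, so the
    per-patient and cohort paths cannot drift apart.
    """
    if isinstance(outcome, str):
        lut = {"progressive": OUTCOME_PROGRESSIVE, "quiescent": OUTCOME_QUIESCENT, "late_stage": OUTCOME_LATE}
        outcome = lut[outcome]
    cohort = pd.DataFrame(
        {
            "id": [patient.id],
            "age": [patient.age],
            "sex": [patient.sex],
            "baseline_utility": [patient.baseline_utility],
            "baseline_fd": [patient.baseline_fd],
            "ectopic": [patient.ectopic],
        }
    )
    res = simulate_cohort(cohort, strategy, np.array([outcome]), params, rng=rng, record=True)
    row = res.summary.iloc[0]
    alive_mask = res.states[0] != State.DEAD
    frame = pd.DataFrame(
        {
            "cycle": np.arange(params.n_cycles),
            "time": res.times,
            "state": [State(s).name for s in res.states[0]],
            "fd": res.fd[0],
            "cost": res.costs[0],
            "utility": res.utilities[0],
            "event": [_event_string(int(c)) for c in res.events[0]],
        }
    )
    # drop cycles after death for a readable event list
    if not alive_mask.all():
        last = int(np.max(np.nonzero(alive_mask)[0])) if alive_mask.any() else -1
        frame = frame.iloc[: last + 1]
    return Trajectory(
        patient_id=patient.id,
        strategy=strategy.name,
        frame=frame,
        courses=int(row["courses"]),
        operations=int(row["operations"]),
        death_time=float(row["death_time"]),
        entered_late=bool(row["entered_late"]),
    )


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Long-format CSV audit trail: one row per patient-strategy-cycle."""
    frames = []
    for tr in trajectories:
        f = tr.frame.copy()
        f.insert(0, "strategy", tr.strategy)
        f.insert(0, "patient_id", tr.patient_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"patient_id", "strategy", "cycle", "time", "state", "fd", "cost", "utility", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns {sorted(missing)}")
    return df
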