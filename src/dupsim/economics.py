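"""Discounting, utilities, cost/QALY accrual and incremental analysis.

Costs and QALYs accrued during the 18-month trial period are undiscounted;
everything beyond is discounted at the configured annual rate (3.5% in the
base case), per UK reference-case practice.  The incremental analysis builds
the standard cost-effectiveness frontier: strategies are sorted by mean cost,
strictly dominated strategies (another strategy costs no more and yields at
least as many QALYs, one strictly) are removed, then extended dominance is
resolved so that frontier ICERs increase strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters
from .states import State, StrategySpec

__all__ = [
    "discount_factor",
    "cycle_utility",
    "trial_accrual",
    "accrue",
    "incremental_analysis",
    "StrategyResult",
    "strategy_table",
]


def discount_factor(t, params: ModelParameters):
    """Discount factor at time ``t`` (years from randomization).

    Equals 1 during the trial period; beyond it,
    ``(1 + r)^-(t - trial_period)``.  Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    over = np.maximum(t_arr - params.trial_period, 0.0)
    out = (1.0 + params.discount_rate) ** (-over)
    return float(out) if np.isscalar(t) else out


def _decrement_lookup(params: ModelParameters) -> np.ndarray:
    ls = params.late_stage
    dec = np.zeros(len(State))
    dec[State.LATE_UNTREATED] = ls.utility_decrement_late_untreated
    dec[State.LATE_POST_PNF_SUCCESS] = ls.utility_decrement_post_pnf_success
    dec[State.LATE_POST_PNF_FAILED] = ls.utility_decrement_post_pnf_failed
    dec[State.LATE_POST_FASCIECTOMY] = ls.utility_decrement_post_fasciectomy
    dec[State.LATE_POST_DERMOFASCIECTOMY] = ls.utility_decrement_post_dermofasciectomy
    return dec


def cycle_utility(state, baseline_utility, params: ModelParameters):
    """Annualized EQ-5D utility occupied in ``state`` (vectorized).

    Early states use the QALY regression
    ``constant + coef * baseline_utility``, plus the quiescence gain while
    quiescent; late states subtract their configured decrement from the
    progressive early-stage utility.  Capped at 1; zero when dead.
    """
    state = np.asarray(state, dtype=np.int64)
    base = params.qaly_reg_constant + params.qaly_reg_baseline_utility_coef * np.asarray(
        baseline_utility, dtype=float
    )
    u = base + params.qaly_gain_quiescence * (state == State.EARLY_QUIESCENT)
    u = u - _decrement_lookup(params)[state]
    u = np.minimum(u, 1.0)
    u = np.where(state == State.DEAD, 0.0, u)
    return u if u.ndim else float(u)


def trial_accrual(
    baseline_utility,
    quiescent,
    strategy: StrategySpec,
    params: ModelParameters,
):
    """Per-patient undiscounted QALYs and costs over the 18-month trial period.

    The same utility regression drives the trial window: the quiescence gain
    is accrued over the final year of the trial (the 6-18 month window the
    regression covers).  Costs comprise a fixed non-intervention background
    cost plus one course of treatment for strategies with an initial course.

    Returns ``(qalys, costs)`` arrays.
    """
    bl = np.asarray(baseline_utility, dtype=float)
    q = np.asarray(quiescent, dtype=bool)
    base = params.qaly_reg_constant + params.qaly_reg_baseline_utility_coef * bl
    first_window = params.trial_period - 1.0  # 0-6 months
    qalys = first_window * np.minimum(base, 1.0) + 1.0 * np.minimum(
        base + params.qaly_gain_quiescence * q, 1.0
    )
    cost = params.trial_background_cost + (params.course_cost if strategy.initial_course else 0.0)
    costs = np.full(bl.shape, cost)
    return qalys, costs


def accrue(trajectory, params: ModelParameters):
    """Discount a simulated trajectory into lifetime model-period cost and QALYs.

    Works from the per-cycle record (undiscounted cycle costs, annualized
    cycle utilities), independently of the engine's internal accumulation, so
    it doubles as an audit of the simulation output.

    Returns ``(discounted_cost, discounted_qalys, event_summary)``.
    """
    frame = trajectory.frame
    alive = frame["state"] != State.DEAD.name
    dfac = discount_factor(frame["time"].to_numpy(), params)
    cost = float(np.sum(frame["cost"].to_numpy() * dfac))
    qalys = float(
        np.sum(frame["utility"].to_numpy()[alive] * params.cycle_length * dfac[alive])
    )
    events = frame.loc[frame["event"] != "", "event"]
    summary = events.str.split("+").explode().value_counts().to_dict()
    return cost, qalys, summary


# ---------------------------------------------------------------------------
# strategy-level results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyResult:
    """Mean (and interval) lifetime outcomes for one strategy.

    Lifetime quantities are the sum of the trial-period and model-period
    components.  Intervals, where present, are 2.5th/97.5th percentiles over
    probabilistic-sensitivity-analysis draws.
    """

    strategy: str
    qalys_trial: float
    qalys_model: float
    costs_trial: float
    costs_model: float
    life_expectancy: float
    years_early_stage: float
    years_free_late_stage: float
    n_courses: float
    n_operations: float
    ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def qalys_lifetime(self) -> float:
        return self.qalys_trial + self.qalys_model

    @property
    def costs_lifetime(self) -> float:
        return self.costs_trial + self.costs_model

    def __post_init__(self) -> None:
        for name in (
            "qalys_trial", "qalys_model", "costs_trial", "costs_model",
            "life_expectancy", "years_early_stage", "years_free_late_stage",
            "n_courses", "n_operations",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def strategy_table(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Publication-style table: one row per outcome, one column per strategy."""
    rows = [
        ("qalys_trial", "QALYs: trial"),
        ("qalys_model", "QALYs: model"),
        ("qalys_lifetime", "QALYs: lifetime"),
        ("costs_trial", "NHS costs, GBP: trial"),
        ("costs_model", "NHS costs, GBP: model"),
        ("costs_lifetime", "NHS costs, GBP: lifetime"),
        ("life_expectancy", "Life expectancy, yrs"),
        ("years_early_stage", "Years with early-stage DD"),
        ("years_free_late_stage", "Years free of late-stage DD"),
        ("n_courses", "Courses of treatment"),
        ("n_operations", "Operations for late-stage DD"),
    ]
    data = {r.strategy: [getattr(r, attr) for attr, _ in rows] for r in results}
    return pd.DataFrame(data, index=[label for _, label in rows])


# ---------------------------------------------------------------------------
# incremental cost-effectiveness analysis
# ---------------------------------------------------------------------------


def _icer(d_cost: float, d_qaly: float) -> float:
    if d_qaly == 0.0:
        return np.nan  # undefined; flagged, never divided
    return d_cost / d_qaly


def incremental_analysis(
    results: Mapping[str, tuple[float, float]] | Sequence[StrategyResult],
    reference: str = "standard_care",
) -> pd.DataFrame:
    """Dominance analysis and frontier ICERs over a set of strategies.

    ``results`` is either a mapping ``name -> (mean_cost, mean_qalys)`` or a
    sequence of :class:`StrategyResult`.  The returned frame is sorted by
    mean cost and carries, per strategy: ``dominated`` (strict dominance),
    ``extended_dominated``, ``icer_frontier`` (vs the previous strategy on
    the efficiency frontier), and ``icer_vs_reference`` (pairwise vs
    ``reference`` where present -- the headline reporting convention).
    """
    if not isinstance(results, Mapping):
        results = {r.strategy: (r.costs_lifetime, r.qalys_lifetime) for r in results}
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least two strategies")

    df = (
        pd.DataFrame(
            [(name, c, q) for name, (c, q) in results.items()],
            columns=["strategy", "cost", "qalys"],
        )
        .sort_values(["cost", "qalys"], ascending=[True, False])
        .reset_index(drop=True)
    )

    # strict dominance
    dominated = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        for j in range(len(df)):
            if i == j:
                continue
            cheaper_eq = df.cost[j] <= df.cost[i] and df.qalys[j] >= df.qalys[i]
            strict = df.cost[j] < df.cost[i] or df.qalys[j] > df.qalys[i]
            if cheaper_eq and strict:
                dominated[i] = True
                break
    df["dominated"] = dominated

    # extended dominance: keep only strategies whose frontier ICERs increase
    frontier = [i for i in range(len(df)) if not dominated[i]]
    changed = True
    ext = np.zeros(len(df), dtype=bool)
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            prev_i, i, next_i = frontier[k - 1], frontier[k], frontier[k + 1]
            icer_in = _icer(df.cost[i] - df.cost[prev_i], df.qalys[i] - df.qalys[prev_i])
            icer_out = _icer(df.cost[next_i] - df.cost[i], df.qalys[next_i] - df.qalys[i])
            if np.isnan(icer_in) or (not np.isnan(icer_out) and icer_out <= icer_in):
                ext[i] = True
                frontier.pop(k)
                changed = True
                break
    df["extended_dominated"] = ext

    icer_frontier = np.full(len(df), np.nan)
    for k in range(1, len(frontier)):
        i, prev_i = frontier[k], frontier[k - 1]
        icer_frontier[i] = _icer(df.cost[i] - df.cost[prev_i], df.qalys[i] - df.qalys[prev_i])
    df["icer_frontier"] = icer_frontier

    if reference in set(df.strategy):
        ref = df.loc[df.strategy == reference].iloc[0]
        df["icer_vs_reference"] = [
            np.nan
            if row.strategy == reference
            else _icer(row.cost - ref.cost, row.qalys - ref.qalys)
            for row in df.itertuples()
        ]
    return df
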