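"""Probabilistic sensitivity analysis, CEAC, value of information, tornado.

The PSA re-runs the patient-level model once per sampled parameter set
(draw); within a draw, every patient is simulated ``n_reps`` times under each
strategy with common random numbers, and the per-draw means of lifetime
discounted cost and QALYs form the PSA sample.  Decision quantities follow
the net-monetary-benefit framework: ``NB = lambda * QALYs - cost`` at
willingness-to-pay ``lambda``.

* CEAC: per ``lambda``, the probability (fraction of draws) that each
  strategy has the highest net benefit; floating-point ties are credited to
  the cheaper strategy.
* EVPI per patient: ``E[max_s NB_s] - max_s E[NB_s]``; non-negative by
  construction.  Population value is the bare product with the number of UK
  prevalent cases (no population discounting).
* EVPPI: single-loop regression estimator -- each strategy's net benefit is
  smoothed on the sampled values of the parameter subset (cubic B-spline
  basis, additive across parameters) and the EVPI formula is applied to the
  fitted values.  A nested two-level Monte Carlo estimator is the natural
  cross-check at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import SplineTransformer

from .cohort import OUTCOME_QUIESCENT, arm_probabilities, generate_cohort, outcome_from_uniform
from .economics import trial_accrual
from .engine import draw_cycle_randoms, replicate_cohort, simulate_cohort
from .params import ModelParameters, ParameterDraws
from .states import DEFAULT_STRATEGIES, StrategySpec

__all__ = [
    "PSASamples",
    "evaluate_strategies",
    "mean_outcomes",
    "run_psa",
    "ceac",
    "evpi_per_patient",
    "evppi",
    "population_value",
    "one_way_sa",
    "pairwise_icer",
    "write_psa",
    "read_psa",
]

_EXTRA_COLS = (
    "qalys_trial",
    "qalys_model",
    "cost_trial",
    "cost_model",
    "life_expectancy",
    "years_early",
    "years_free_late",
    "courses",
    "operations",
)


def evaluate_strategies(
    cohort: pd.DataFrame,
    params: ModelParameters,
    strategies: Sequence[StrategySpec] = DEFAULT_STRATEGIES,
    n_reps: int = 1,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate all strategies on a cohort with common random numbers.

    Returns, per strategy, one row per simulated individual with trial-period,
    model-period and lifetime costs/QALYs plus event summaries.  The same
    outcome deviate and cycle random streams are shared across strategies.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rep = replicate_cohort(cohort, n_reps)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    u_outcome = rng.random(len(rep))
    randoms = draw_cycle_randoms(rng, len(rep), params.n_cycles)

    out: dict[str, pd.DataFrame] = {}
    for s in strategies:
        p_late, p_q = arm_probabilities(s, params)
        outcomes = outcome_from_uniform(u_outcome, p_late, p_q)
        res = simulate_cohort(rep, s, outcomes, params, randoms=randoms)
        tq, tc = trial_accrual(
            rep["baseline_utility"].to_numpy(), outcomes == OUTCOME_QUIESCENT, s, params
        )
        df = res.summary.copy()
        df["qalys_trial"] = tq
        df["cost_trial"] = tc
        df["qalys_lifetime"] = df["qalys_trial"] + df["qalys_model"]
        df["cost_lifetime"] = df["cost_trial"] + df["cost_model"]
        df["life_expectancy"] = params.trial_period + df["life_years"]
        # every patient is early-stage and late-stage-free throughout the trial
        df["years_early"] = params.trial_period + df["years_early"]
        df["years_free_late"] = params.trial_period + df["years_free_late"]
        out[s.name] = df
    return out


def mean_outcomes(per_individual: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Collapse :func:`evaluate_strategies` output to per-strategy means."""
    cols = ["cost_lifetime", "qalys_lifetime", *_EXTRA_COLS]
    rows = {name: df[cols].mean() for name, df in per_individual.items()}
    return pd.DataFrame(rows).T.rename_axis("strategy")


def pairwise_icer(means: pd.DataFrame, strategy: str, reference: str) -> float:
    """ICER of ``strategy`` vs ``reference`` from a mean-outcomes table."""
    d_cost = means.loc[strategy, "cost_lifetime"] - means.loc[reference, "cost_lifetime"]
    d_qaly = means.loc[strategy, "qalys_lifetime"] - means.loc[reference, "qalys_lifetime"]
    return float("nan") if d_qaly == 0 else float(d_cost / d_qaly)


@dataclass
class PSASamples:
    """Per-draw, per-strategy mean lifetime outcomes (the PSA output matrix)."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies) mean discounted lifetime cost
    qalys: np.ndarray  # (n_draws, n_strategies) mean discounted lifetime QALYs
    extras: Mapping[str, np.ndarray] = field(default_factory=dict)
    param_table: pd.DataFrame | None = None
    n_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        S = len(self.strategies)
        if self.costs.shape != self.qalys.shape or self.costs.shape[1] != S:
            raise ValueError("costs/qalys must be (n_draws, n_strategies)")
        if not (np.isfinite(self.costs).all() and np.isfinite(self.qalys).all()):
            raise ValueError("PSA samples must be finite")

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def net_benefit(self, wtp: float) -> np.ndarray:
        return wtp * self.qalys - self.costs

    def column(self, strategy: str) -> int:
        return self.strategies.index(strategy) if isinstance(self.strategies, list) else list(self.strategies).index(strategy)


def run_psa(
    cohort: pd.DataFrame,
    draws: ParameterDraws,
    strategies: Sequence[StrategySpec] = DEFAULT_STRATEGIES,
    n_reps: int = 100,
    seed: int = 0,
) -> PSASamples:
    """Run the patient-level model once per PSA draw.

    Each draw simulates the whole cohort ``n_reps`` times per strategy with
    common random numbers across strategies; per-draw cohort means are
    recorded.  Deterministic under fixed ``(cohort, draws, n_reps, seed)``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = tuple(s.name for s in strategies)
    D, S = draws.n_draws, len(names)
    costs = np.empty((D, S))
    qalys = np.empty((D, S))
    extras = {c: np.empty((D, S)) for c in _EXTRA_COLS}
    children = np.random.SeedSequence(seed).spawn(D)
    for d, p in enumerate(draws.realizations):
        per = evaluate_strategies(cohort, p, strategies, n_reps=n_reps, seed=children[d])
        means = mean_outcomes(per)
        for j, name in enumerate(names):
            costs[d, j] = means.loc[name, "cost_lifetime"]
            qalys[d, j] = means.loc[name, "qalys_lifetime"]
            for c in _EXTRA_COLS:
                extras[c][d, j] = means.loc[name, c]
    return PSASamples(
        strategies=names,
        costs=costs,
        qalys=qalys,
        extras=extras,
        param_table=draws.table.copy(),
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# decision analysis over PSA samples
# ---------------------------------------------------------------------------


def _cost_order(samples: PSASamples) -> np.ndarray:
    """Strategy column order by increasing mean cost (tie-break convention)."""
    return np.argsort(samples.costs.mean(axis=0), kind="stable")


def ceac(samples: PSASamples, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves and frontier.

    Per willingness-to-pay, the probability that each strategy has maximal
    net benefit (ties credited to the cheaper strategy) and whether it
    maximizes *expected* net benefit (the frontier).
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one draw")
    order = _cost_order(samples)
    rows = []
    for wtp in wtp_grid:
        nb = samples.net_benefit(float(wtp))
        winner = order[np.argmax(nb[:, order], axis=1)]
        frontier = order[int(np.argmax(nb.mean(axis=0)[order]))]
        for j, name in enumerate(samples.strategies):
            rows.append(
                {
                    "wtp": float(wtp),
                    "strategy": name,
                    "probability": float(np.mean(winner == j)),
                    "on_frontier": bool(j == frontier),
                }
            )
    return pd.DataFrame(rows)


def evpi_per_patient(samples: PSASamples, wtp: float) -> float:
    """Expected value of perfect information per patient at ``wtp``.

    ``E[max_s NB] - max_s E[NB]``; the expected net-benefit loss from
    deciding now rather than under certainty.
    """
    if samples.n_draws < 2:
        raise ValueError("EVPI needs at least two draws")
    nb = samples.net_benefit(wtp)
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def _smooth_basis(x: np.ndarray) -> np.ndarray:
    """Regression basis for one parameter: dummies if near-discrete, else cubic splines."""
    uniq = np.unique(x)
    if uniq.size <= 5:
        return (x[:, None] == uniq[None, 1:]).astype(float)
    n_knots = int(min(5, uniq.size))
    st = SplineTransformer(n_knots=n_knots, degree=3, include_bias=False)
    return st.fit_transform(x[:, None])


def evppi(
    samples: PSASamples,
    param_subset: Sequence[str],
    wtp: float,
    param_table: pd.DataFrame | None = None,
) -> float:
    """Expected value of partial perfect information for a parameter subset.

    Single-loop estimator: each strategy's net benefit is regressed on an
    additive spline basis of the subset's sampled values; the EVPI formula is
    applied to the fitted (conditional-mean) net benefits.  Clipped at zero.
    """
    if len(param_subset) == 0:
        raise ValueError("param_subset must not be empty")
    table = param_table if param_table is not None else samples.param_table
    if table is None:
        raise ValueError("no parameter table available for EVPPI")
    missing = set(param_subset) - set(table.columns)
    if missing:
        raise ValueError(f"parameters not in PSA sample: {sorted(missing)}")
    nb = samples.net_benefit(wtp)
    basis = np.hstack([_smooth_basis(table[p].to_numpy(dtype=float)) for p in param_subset])
    fitted = LinearRegression().fit(basis, nb).predict(basis)
    value = fitted.max(axis=1).mean() - fitted.mean(axis=0).max()
    return float(max(value, 0.0))


def population_value(per_patient: float, population: int) -> float:
    """Scale a per-patient value of information to a population: bare product."""
    if per_patient < 0 or population < 0:
        raise ValueError("per_patient and population must be non-negative")
    return float(per_patient) * float(population)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


def one_way_sa(
    base: ModelParameters,
    cohort: pd.DataFrame | None = None,
    param_ranges: Mapping[str, tuple[float, float]] | None = None,
    strategy: str = "adalimumab_repeat",
    reference: str = "standard_care",
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Tornado analysis: the ICER of ``strategy`` vs ``reference`` with each
    uncertain parameter at its lower and upper bound, all else at base.

    Default ranges are each parameter's 95% interval (or stated sensitivity
    range).  Rows are sorted by the width of the ICER span.  The same seed
    (hence the same simulation noise) is reused for every run, so differences
    reflect the parameter change only.
    """
    if cohort is None:
        cohort = generate_cohort(seed=seed)
    if param_ranges is None:
        param_ranges = {
            name: spec.get("ci95", spec.get("range"))
            for name, spec in base.uncertainty.items()
        }
    strategies = DEFAULT_STRATEGIES

    def icer_for(p: ModelParameters) -> float:
        means = mean_outcomes(evaluate_strategies(cohort, p, strategies, n_reps=n_reps, seed=seed))
        return pairwise_icer(means, strategy, reference)

    base_icer = icer_for(base)
    rows = []
    for name, (lo, hi) in param_ranges.items():
        icer_lo = icer_for(base.replace(**{name: float(lo)}))
        icer_hi = icer_for(base.replace(**{name: float(hi)}))
        span = abs(
            (icer_hi if np.isfinite(icer_hi) else base_icer)
            - (icer_lo if np.isfinite(icer_lo) else base_icer)
        )
        rows.append(
            {
                "parameter": name,
                "low": float(lo),
                "high": float(hi),
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "span": span,
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False).reset_index(drop=True)
    df.attrs["base_icer"] = base_icer
    return df


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------


def write_psa(samples: PSASamples, path: str | Path) -> None:
    """Long-format PSA CSV: draw, strategy, mean_cost, mean_qaly (+ extras)."""
    rows = []
    for d in range(samples.n_draws):
        for j, name in enumerate(samples.strategies):
            row = {
                "draw": d,
                "strategy": name,
                "mean_cost": samples.costs[d, j],
                "mean_qaly": samples.qalys[d, j],
            }
            for c, arr in samples.extras.items():
                row[c] = arr[d, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_psa(path: str | Path, param_table: pd.DataFrame | None = None) -> PSASamples:
    df = pd.read_csv(path)
    names = tuple(dict.fromkeys(df["strategy"]))
    D = df["draw"].nunique()
    costs = np.empty((D, len(names)))
    qalys = np.empty((D, len(names)))
    extra_cols = [c for c in df.columns if c not in ("draw", "strategy", "mean_cost", "mean_qaly")]
    extras = {c: np.empty((D, len(names))) for c in extra_cols}
    for j, name in enumerate(names):
        sub = df[df["strategy"] == name].sort_values("draw")
        costs[:, j] = sub["mean_cost"].to_numpy()
        qalys[:, j] = sub["mean_qaly"].to_numpy()
        for c in extra_cols:
            extras[c][:, j] = sub[c].to_numpy()
    return PSASamples(strategies=names, costs=costs, qalys=qalys, extras=extras, param_table=param_table)
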