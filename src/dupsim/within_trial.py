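"""Within-trial cost-utility analysis on synthetic trial data.

Reproduces the 12-month trial-based pipeline: EQ-5D utilities collected at
baseline and 3, 6, 9 and 12 months (18 months is also generated) are turned
into QALYs by the trapezoidal area under the utility-time curve; arm
differences in QALYs and NHS/PSS costs are estimated by linear regression
adjusted for site, age and (QALYs only) baseline utility; joint uncertainty
is propagated by non-parametric bootstrapping with resampling stratified by
arm, yielding percentile intervals, the ICER and a within-trial CEAC.

The trial's individual-patient data are not public; a synthetic generator
emulates its headline marginals (12-month QALY means ~0.875 adalimumab vs
~0.855 standard care, adalimumab injection costs ~GBP 2,030, negligible
other NHS resource use).  The synthetic data are complete, so no missing-data
imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .params import ValidationError

__all__ = [
    "TrialSpec",
    "CUAResult",
    "generate_trial_dataset",
    "qalys_auc",
    "adjusted_difference",
    "bootstrap_cua",
    "write_trial_dataset",
    "read_trial_dataset",
    "UTILITY_MONTHS",
]

EQ5D_FLOOR = -0.594
UTILITY_MONTHS = (0, 3, 6, 9, 12, 18)
_UTILITY_COLS = tuple(f"utility_m{m}" for m in UTILITY_MONTHS)
_COST_COLS = ("cost_injections", "cost_surgery", "cost_gp", "cost_physio")


@dataclass(frozen=True)
class TrialSpec:
    """Recipe for a synthetic two-arm trial dataset.

    Visit utilities are drawn from Beta distributions rescaled to the EQ-5D
    index range around a participant-level mean, so expectations are exact
    (no clipping bias).  ``arm_qaly_effect`` is the true treatment effect on
    12-month QALYs; the per-visit utility shift implied by the trapezoid
    weights is applied from month 3 onwards.
    """

    n_per_arm: int = 70
    n_sites: int = 2
    age_mean: float = 61.0
    age_sd: float = 9.0
    age_min: float = 30.0
    placebo_utility_mean: float = 0.855
    ada_baseline_shift: float = 0.016  # baseline imbalance, handled by adjustment
    arm_qaly_effect: float = 0.004  # true arm effect on 12-month QALYs
    participant_utility_sd: float = 0.11
    visit_concentration: float = 150.0  # Beta concentration of visits around the mean
    injection_cost_mean: float = 2030.0
    injection_cost_sd: float = 360.0
    p_surgery: float = 0.015
    surgery_cost_mean: float = 2500.0
    surgery_cost_sd: float = 500.0
    p_gp: float = 0.02
    gp_visit_cost: float = 39.0
    p_physio: float = 0.02
    physio_visit_cost: float = 45.0

    def validate(self) -> None:
        if self.n_per_arm < 0 or self.n_sites < 1:
            raise ValidationError("n_per_arm must be >= 0 and n_sites >= 1")
        for name in ("p_surgery", "p_gp", "p_physio"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        for name in ("placebo_utility_mean",):
            if not EQ5D_FLOOR < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} outside the EQ-5D index range")
        if self.participant_utility_sd <= 0 or self.visit_concentration <= 0:
            raise ValidationError("scale parameters must be positive")
        if self.injection_cost_mean < 0 or self.injection_cost_sd <= 0:
            raise ValidationError("injection cost parameters invalid")


def _beta_on_interval(
    rng: np.random.Generator,
    mean: np.ndarray,
    *,
    sd: float | None = None,
    concentration: float | None = None,
    lo: float = EQ5D_FLOOR,
    hi: float = 1.0,
) -> np.ndarray:
    """Beta draw rescaled to [lo, hi] with exact mean ``mean``."""
    m = (np.asarray(mean, dtype=float) - lo) / (hi - lo)
    m = np.clip(m, 1e-3, 1.0 - 1e-3)
    if concentration is None:
        s_unit = sd / (hi - lo)
        concentration = m * (1.0 - m) / s_unit**2 - 1.0
    a = m * concentration
    b = (1.0 - m) * concentration
    return lo + (hi - lo) * rng.beta(a, b)


# trapezoid weights of each visit in 12-month QALYs (times in years)
_TRAPEZOID_12M = np.array([0.125, 0.25, 0.25, 0.25, 0.125])
#: share of the 12-month QALY effect carried by post-baseline visits
_POST_BASELINE_WEIGHT = float(_TRAPEZOID_12M[1:].sum())


def generate_trial_dataset(spec: TrialSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a complete synthetic trial dataset; deterministic under seed.

    One row per participant: arm, site, age, utilities at each visit, and
    12-month NHS/PSS cost components.
    """
    spec = spec or TrialSpec()
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = 2 * spec.n_per_arm
    arm = np.repeat(["adalimumab", "placebo"], spec.n_per_arm)
    site = np.tile(np.arange(spec.n_sites), n // spec.n_sites + 1)[:n]
    age = np.maximum(rng.normal(spec.age_mean, spec.age_sd, n), spec.age_min)

    is_ada = arm == "adalimumab"
    mean_util = np.where(
        is_ada,
        spec.placebo_utility_mean + spec.ada_baseline_shift,
        spec.placebo_utility_mean,
    )
    m_i = _beta_on_interval(rng, mean_util, sd=spec.participant_utility_sd)
    m_i = np.clip(m_i, EQ5D_FLOOR + 0.02, 0.995)

    # per-visit utility shift so the injected 12-month QALY effect is exact
    delta = spec.arm_qaly_effect / _POST_BASELINE_WEIGHT
    data: dict[str, np.ndarray] = {}
    for month in UTILITY_MONTHS:
        mean_visit = m_i + (delta * is_ada if month > 0 else 0.0)
        mean_visit = np.clip(mean_visit, EQ5D_FLOOR + 0.02, 0.9985)
        data[f"utility_m{month}"] = _beta_on_interval(
            rng, mean_visit, concentration=spec.visit_concentration
        )

    inj_sd, inj_mean = spec.injection_cost_sd, spec.injection_cost_mean
    shape = (inj_mean / inj_sd) ** 2
    cost_inj = np.where(is_ada, rng.gamma(shape, inj_sd**2 / inj_mean, n), 0.0)
    cost_surgery = np.where(
        rng.random(n) < spec.p_surgery,
        np.maximum(rng.normal(spec.surgery_cost_mean, spec.surgery_cost_sd, n), 0.0),
        0.0,
    )
    cost_gp = np.where(rng.random(n) < spec.p_gp, spec.gp_visit_cost * rng.integers(1, 3, n), 0.0)
    cost_physio = np.where(
        rng.random(n) < spec.p_physio, spec.physio_visit_cost * rng.integers(1, 4, n), 0.0
    )

    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "arm": arm,
            "site": site,
            "age": age,
            **data,
            "cost_injections": cost_inj,
            "cost_surgery": cost_surgery,
            "cost_gp": cost_gp,
            "cost_physio": cost_physio,
        }
    )
    df["cost_total"] = df[list(_COST_COLS)].sum(axis=1)
    return df


def qalys_auc(utilities: Sequence[float] | np.ndarray, times: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """QALYs as the trapezoidal area under the utility curve.

    ``times`` are in months, strictly increasing; the result is in
    QALYs (utility-years).  ``utilities`` may be 2-D (rows = participants).
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(utilities, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    years = t / 12.0
    out = np.trapezoid(u, years, axis=-1)
    return float(out) if out.ndim == 0 else out


def _with_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Attach 12-month QALYs (AUC over months 0-12) and total costs."""
    df = df.copy()
    months = [m for m in UTILITY_MONTHS if m <= 12]
    u = df[[f"utility_m{m}" for m in months]].to_numpy()
    df["qalys"] = qalys_auc(u, months)
    df["baseline_utility"] = df["utility_m0"]
    if "cost_total" not in df.columns:
        df["cost_total"] = df[list(_COST_COLS)].sum(axis=1)
    return df


def adjusted_difference(
    dataset: pd.DataFrame,
    outcome: str = "qalys",
    covariates: Sequence[str] | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Covariate-adjusted arm difference (adalimumab minus standard care).

    Ordinary least squares of the participant-level outcome on the arm
    indicator plus covariates -- site and age, and baseline utility for
    QALYs only.  Returns ``(estimate, se, normal_ci)``; bootstrap intervals
    come from :func:`bootstrap_cua`.
    """
    if outcome not in ("qalys", "costs"):
        raise ValueError("outcome must be 'qalys' or 'costs'")
    df = _with_outcomes(dataset)
    y = "qalys" if outcome == "qalys" else "cost_total"
    if covariates is None:
        covariates = ["C(site)", "age"] + (["baseline_utility"] if outcome == "qalys" else [])
    formula = f"{y} ~ C(arm, Treatment(reference='placebo'))" + "".join(f" + {c}" for c in covariates)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("collinear covariates in adjustment model")
    fit = model.fit()
    term = "C(arm, Treatment(reference='placebo'))[T.adalimumab]"
    est = float(fit.params[term])
    se = float(fit.bse[term])
    lo, hi = fit.conf_int().loc[term]
    return est, se, (float(lo), float(hi))


def _design(df: pd.DataFrame, with_baseline: bool) -> np.ndarray:
    """Fast design matrix for the bootstrap loop (intercept, arm, sites, age[, baseline])."""
    cols = [np.ones(len(df)), (df["arm"] == "adalimumab").to_numpy(dtype=float)]
    for s in sorted(df["site"].unique())[1:]:
        cols.append((df["site"] == s).to_numpy(dtype=float))
    cols.append(df["age"].to_numpy(dtype=float))
    if with_baseline:
        cols.append(df["baseline_utility"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _arm_coef(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


@dataclass(frozen=True)
class CUAResult:
    """Within-trial cost-utility analysis output."""

    qaly_diff: float
    qaly_ci: tuple[float, float]
    cost_diff: float
    cost_ci: tuple[float, float]
    icer: float
    ceac: pd.DataFrame  # columns: wtp, probability
    replicates: pd.DataFrame  # columns: qaly_diff, cost_diff
    n_boot: int
    seed: int

    def prob_cost_effective(self, wtp: float) -> float:
        row = self.ceac.loc[np.isclose(self.ceac["wtp"], wtp)]
        if row.empty:
            raise KeyError(f"wtp {wtp} not on the CEAC grid")
        return float(row["probability"].iloc[0])


def bootstrap_cua(
    dataset: pd.DataFrame,
    n_boot: int = 5000,
    wtp_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> CUAResult:
    """Bootstrap the within-trial cost-utility analysis.

    Participants are resampled with replacement within arm; per replicate the
    adjusted QALY and cost differences are recomputed.  The ICER point
    estimate is the ratio of the full-sample adjusted mean differences; the
    CEAC is the fraction of replicates with positive incremental net benefit
    at each willingness-to-pay.  Replicates with an exactly zero QALY
    difference stay in the CEAC but are excluded from ratio summaries.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if wtp_grid is None:
        wtp_grid = np.arange(0, 50001, 1000, dtype=float)
    df = _with_outcomes(dataset)
    qaly_est, _, _ = adjusted_difference(dataset, "qalys")
    cost_est, _, _ = adjusted_difference(dataset, "costs")
    icer = float("nan") if qaly_est == 0 else cost_est / qaly_est

    X_q = _design(df, with_baseline=True)
    X_c = _design(df, with_baseline=False)
    y_q = df["qalys"].to_numpy(dtype=float)
    y_c = df["cost_total"].to_numpy(dtype=float)
    arm_idx = {arm: np.flatnonzero(df["arm"] == arm) for arm in df["arm"].unique()}

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reps = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ix, size=ix.size, replace=True) for ix in arm_idx.values()])
        reps[b, 0] = _arm_coef(X_q[idx], y_q[idx])
        reps[b, 1] = _arm_coef(X_c[idx], y_c[idx])
    replicates = pd.DataFrame(reps, columns=["qaly_diff", "cost_diff"])

    qaly_ci = tuple(np.percentile(replicates["qaly_diff"], [2.5, 97.5]))
    cost_ci = tuple(np.percentile(replicates["cost_diff"], [2.5, 97.5]))
    ceac_rows = [
        {
            "wtp": float(w),
            "probability": float(np.mean(w * reps[:, 0] - reps[:, 1] > 0)),
        }
        for w in wtp_grid
    ]
    return CUAResult(
        qaly_diff=qaly_est,
        qaly_ci=(float(qaly_ci[0]), float(qaly_ci[1])),
        cost_diff=cost_est,
        cost_ci=(float(cost_ci[0]), float(cost_ci[1])),
        icer=icer,
        ceac=pd.DataFrame(ceac_rows),
        replicates=replicates,
        n_boot=n_boot,
        seed=seed,
    )


def write_trial_dataset(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False)


def read_trial_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "arm", "site", "age", *_UTILITY_COLS, *_COST_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trial dataset missing columns {sorted(missing)}")
    return df
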