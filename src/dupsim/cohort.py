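"""Synthetic trial cohort generation and 18-month outcome assignment.

The trial's individual-patient data are not public, so the model runs on a
synthetic cohort statistically emulating the 69 UK placebo-arm participants
with complete baseline data: adults with an active extensor deficit of at
most 30 degrees and a progressive palmar nodule.  The default marginals
(documented, fully configurable) are a plausible assumption, not estimates.

At 18 months each patient is assigned one of three outcomes -- still
progressive, quiescent, or late-stage -- with arm-specific probabilities.  A
*single* uniform deviate per patient is shared across treatment strategies
(common random numbers), so a patient who is quiescent under standard care is
also quiescent under adalimumab whenever the adalimumab quiescence
probability is at least as large.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import ModelParameters, ValidationError
from .states import StrategySpec, DEFAULT_STRATEGIES

__all__ = [
    "Patient",
    "CohortSpec",
    "generate_cohort",
    "assign_initial_outcomes",
    "outcome_from_uniform",
    "arm_probabilities",
    "write_cohort",
    "read_cohort",
    "OUTCOME_PROGRESSIVE",
    "OUTCOME_QUIESCENT",
    "OUTCOME_LATE",
    "OUTCOME_LABELS",
]

# outcome category codes (order matters for the coupled sampler)
OUTCOME_PROGRESSIVE, OUTCOME_QUIESCENT, OUTCOME_LATE = 0, 1, 2
OUTCOME_LABELS = {OUTCOME_PROGRESSIVE: "progressive", OUTCOME_QUIESCENT: "quiescent", OUTCOME_LATE: "late_stage"}

EQ5D_FLOOR = -0.594  # worst health state of the EQ-5D-5L index

COHORT_COLUMNS = ["id", "age", "sex", "baseline_utility", "baseline_fd", "ectopic"]


@dataclass(frozen=True)
class Patient:
    """Baseline characteristics of one synthetic trial participant."""

    id: int
    age: float
    sex: str
    baseline_utility: float
    baseline_fd: float
    ectopic: bool

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError("age must be >= 18")
        if not 0.0 <= self.baseline_fd <= 30.0:
            raise ValidationError("baseline flexion deformity must lie in [0, 30] degrees")
        if not EQ5D_FLOOR <= self.baseline_utility <= 1.0:
            raise ValidationError(f"baseline_utility outside [{EQ5D_FLOOR}, 1]")
        if self.sex not in ("male", "female"):
            raise ValidationError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for a synthetic cohort.

    Defaults are plausible for a UK early-stage Dupuytren's trial population:
    age Normal(61, 9) truncated below at 30, 80% male, baseline EQ-5D utility
    Normal(0.82, 0.15) truncated above at 1, 25% ectopic-disease prevalence,
    baseline flexion deformity Uniform(0, 20) degrees.
    """

    n: int = 69
    age_mean: float = 61.0
    age_sd: float = 9.0
    age_min: float = 30.0
    prop_male: float = 0.80
    utility_mean: float = 0.82
    utility_sd: float = 0.15
    ectopic_prevalence: float = 0.25
    fd_min: float = 0.0
    fd_max: float = 20.0

    def validate(self) -> None:
        if self.n < 0:
            raise ValidationError("cohort size n must be >= 0")
        for name in ("prop_male", "ectopic_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.age_sd <= 0 or self.utility_sd <= 0:
            raise ValidationError("scale parameters must be positive")
        if not 0.0 <= self.fd_min <= self.fd_max <= 30.0:
            raise ValidationError("baseline flexion deformity range must lie within [0, 30]")
        if self.age_min < 18:
            raise ValidationError("age_min must be >= 18")


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort; deterministic under a fixed seed.

    Returns a DataFrame with columns ``id, age, sex, baseline_utility,
    baseline_fd, ectopic``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = spec.n
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < spec.prop_male, "male", "female")
    lo = (EQ5D_FLOOR - spec.utility_mean) / spec.utility_sd
    hi = (1.0 - spec.utility_mean) / spec.utility_sd
    utility = stats.truncnorm.rvs(lo, hi, loc=spec.utility_mean, scale=spec.utility_sd, size=n, random_state=rng)
    fd = rng.uniform(spec.fd_min, spec.fd_max, size=n)
    ectopic = rng.random(n) < spec.ectopic_prevalence
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "baseline_utility": utility,
            "baseline_fd": fd,
            "ectopic": ectopic,
        }
    )


def outcome_from_uniform(u: np.ndarray, p_late: float, p_quiescent: float) -> np.ndarray:
    """Map one uniform deviate per patient to an 18-month outcome category.

    ``late_stage`` if ``u < p_late``; ``quiescent`` if ``u >= 1 - p_quiescent``;
    ``progressive`` otherwise.  This ordering makes the late-stage and
    quiescent categories each monotone in their own probability under common
    random numbers: raising ``p_quiescent`` only ever converts progressive
    patients into quiescent ones.
    """
    u = np.asarray(u)
    out = np.full(u.shape, OUTCOME_PROGRESSIVE, dtype=np.int64)
    out[u < p_late] = OUTCOME_LATE
    out[u >= 1.0 - p_quiescent] = OUTCOME_QUIESCENT
    return out


def arm_probabilities(strategy: StrategySpec, params: ModelParameters) -> tuple[float, float]:
    """(p_late, p_quiescent) at 18 months for a strategy's treatment arm."""
    if strategy.initial_course:
        return params.p_late_ada, params.p_quiescent_ada
    return params.p_late_placebo, params.p_quiescent_placebo


def assign_initial_outcomes(
    cohort: pd.DataFrame,
    params: ModelParameters,
    rng: np.random.Generator,
    strategies: Sequence[StrategySpec] = DEFAULT_STRATEGIES,
) -> pd.DataFrame:
    """Assign each patient's 18-month outcome under every strategy.

    One uniform deviate per patient is shared across strategies (common
    random numbers).  Returns a DataFrame of category codes with one column
    per strategy name, indexed like ``cohort``.
    """
    u = rng.random(len(cohort))
    out = {}
    for s in strategies:
        p_late, p_q = arm_probabilities(s, params)
        out[s.name] = outcome_from_uniform(u, p_late, p_q)
    return pd.DataFrame(out, index=cohort.index)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort file missing columns {sorted(missing)}")
    df["ectopic"] = df["ectopic"].astype(bool)
    return df[COHORT_COLUMNS]
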