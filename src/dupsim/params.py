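"""Model inputs: loading, validation and probabilistic sampling.

Every number the simulation consumes lives in a :class:`ModelParameters`
instance built from YAML/JSON configuration.  Each input carries a provenance
tag; inputs estimated on trial data additionally carry a 95% interval that
drives the probabilistic sensitivity analysis (PSA).

PSA distribution families
-------------------------
The source analysis propagated uncertainty with bootstrap replicates that are
not available here, so parametric families are calibrated to the published
point estimates and interval widths:

* the four 18-month outcome probabilities are sampled *jointly* per arm from a
  three-category Dirichlet (late-stage / quiescent / still-progressive) whose
  concentration is matched to the printed interval widths, guaranteeing
  ``p_late + p_quiescent <= 1`` in every draw;
* regression coefficients and the quiescence utility gain are Normal with
  ``sd = (upper - lower) / 3.92``;
* the residual RMSE of the flexion-deformity regression is fixed (no interval
  is published);
* the duration of quiescence is Uniform(1.5, 5) years;
* placeholder late-stage probabilities and utility decrements are Beta, unit
  costs Gamma, and the mortality hazard ratio log-Normal, each moment-matched
  to the interval recorded in the placeholder config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "LateStageParams",
    "MortalityParams",
    "ModelParameters",
    "ParameterDraws",
    "load_parameters",
    "sample_psa",
    "spawn_seeds",
    "RIDD_PARAMETERS",
]


class ConfigurationError(ValueError):
    """Raised when a configuration file is missing or malformed."""


class ValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


PROVENANCE_TAGS = frozenset(
    {"paper_table_III", "paper_table_I", "paper_methods", "placeholder_literature"}
)

#: half-width of a 95% Normal interval, in standard deviations (2 x 1.96)
_Z95 = 3.92

#: parameters estimated on the trial sample, plus the duration of quiescence --
#: the subset whose EVPPI corresponds to the value of a confirmatory trial
RIDD_PARAMETERS = (
    "p_late_placebo",
    "p_quiescent_placebo",
    "p_late_ada",
    "p_quiescent_ada",
    "qaly_gain_quiescence",
    "qaly_reg_baseline_utility_coef",
    "qaly_reg_constant",
    "fd_change_constant",
    "fd_change_ectopic_coef",
    "quiescence_duration",
)


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LateStageParams:
    """Late-stage disease pathway inputs (all placeholder literature values)."""

    p_elect_surgery: float
    p_pnf_success: float
    p_relapse_pnf: float
    p_relapse_fasciectomy: float
    p_relapse_dermofasciectomy: float
    cost_pnf: float
    cost_limited_fasciectomy: float
    cost_dermofasciectomy: float
    cost_surgery_followup: float
    utility_decrement_late_untreated: float
    utility_decrement_post_pnf_success: float
    utility_decrement_post_pnf_failed: float
    utility_decrement_post_fasciectomy: float
    utility_decrement_post_dermofasciectomy: float

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ValidationError(f"late_stage.{f.name}={v} outside [0, 1]")
            if f.name.startswith("cost_") and v < 0:
                raise ValidationError(f"late_stage.{f.name}={v} negative")
            if f.name.startswith("utility_decrement") and not 0.0 <= v <= 1.0:
                raise ValidationError(f"late_stage.{f.name}={v} outside [0, 1]")


@dataclass(frozen=True)
class MortalityParams:
    """Background mortality: synthetic Gompertz life table plus disease hazard ratio.

    The default annual hazard is ``gompertz_rate * exp(gompertz_shape * age)``
    (unisex).  A user-supplied life table (columns ``age``, ``sex``,
    ``hazard``) overrides the Gompertz form; ages beyond the table maximum are
    treated as certain death within the cycle.
    """

    gompertz_rate: float
    gompertz_shape: float
    dd_hazard_ratio: float
    life_table: pd.DataFrame | None = None

    def validate(self) -> None:
        if self.gompertz_rate <= 0 or self.gompertz_shape <= 0:
            raise ValidationError("Gompertz parameters must be positive")
        if self.dd_hazard_ratio <= 0:
            raise ValidationError("dd_hazard_ratio must be positive")
        if self.life_table is not None:
            missing = {"age", "sex", "hazard"} - set(self.life_table.columns)
            if missing:
                raise ValidationError(f"life_table missing columns {sorted(missing)}")

    def annual_hazard(self, age: np.ndarray | float, sex: np.ndarray | None = None) -> np.ndarray:
        """All-cause annual hazard at ``age`` (before the disease hazard ratio)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        if self.life_table is None:
            return self.gompertz_rate * np.exp(self.gompertz_shape * age)
        tab = self.life_table
        if sex is None:
            sex = np.full(age.shape, "", dtype=object)
        age, sex = np.broadcast_arrays(age, np.asarray(sex, dtype=object))
        out = np.full(age.shape, np.inf)
        ages = np.floor(age).astype(int)
        for s, grp in tab.groupby("sex"):
            lut = grp.set_index(grp["age"].astype(int))["hazard"]
            sel = (sex == s) if (sex != "").any() else np.ones(age.shape, bool)
            a = ages[sel]
            vals = lut.reindex(a).to_numpy(dtype=float)
            vals[a > lut.index.max()] = np.inf  # beyond table: certain death
            vals[np.isnan(vals)] = np.inf
            out[sel] = vals
        return out


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated set of model inputs.

    ``uncertainty`` maps a parameter name to its PSA specification (interval,
    distribution family); ``provenance`` maps every input to its source tag.
    """

    # 18-month outcome probabilities
    p_late_placebo: float
    p_quiescent_placebo: float
    p_late_ada: float
    p_quiescent_ada: float
    # QALY regression (6-18 month window, annualized)
    qaly_gain_quiescence: float
    qaly_reg_baseline_utility_coef: float
    qaly_reg_constant: float
    # flexion-deformity change regression (degrees per 18 months)
    fd_change_constant: float
    fd_change_ectopic_coef: float
    fd_change_rmse: float
    # schedule / structure
    quiescence_duration: float
    cycle_length: float
    horizon: float
    trial_period: float
    discount_rate: float
    late_stage_threshold: float
    # costs
    cost_per_dose: float
    doses_per_course: int
    trial_background_cost: float
    # population scaling / decision thresholds
    uk_prevalent_cases: int
    wtp_grid: tuple[float, ...]
    # sub-records
    late_stage: LateStageParams = None  # type: ignore[assignment]
    mortality: MortalityParams = None  # type: ignore[assignment]
    # metadata
    uncertainty: Mapping[str, Mapping[str, Any]] = field(default_factory=dict, repr=False)
    provenance: Mapping[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def course_cost(self) -> float:
        """Cost of one course of treatment (doses_per_course x cost_per_dose)."""
        return self.doses_per_course * self.cost_per_dose

    @property
    def n_cycles(self) -> int:
        """Number of 6-month model cycles between trial end and horizon."""
        return round((self.horizon - self.trial_period) / self.cycle_length)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        probs = {
            "p_late_placebo": self.p_late_placebo,
            "p_quiescent_placebo": self.p_quiescent_placebo,
            "p_late_ada": self.p_late_ada,
            "p_quiescent_ada": self.p_quiescent_ada,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.p_late_placebo + self.p_quiescent_placebo > 1.0 + 1e-12:
            raise ValidationError("placebo arm: p_late + p_quiescent > 1")
        if self.p_late_ada + self.p_quiescent_ada > 1.0 + 1e-12:
            raise ValidationError("adalimumab arm: p_late + p_quiescent > 1")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be positive")
        n = (self.horizon - self.trial_period) / self.cycle_length
        if abs(n - round(n)) > 1e-9 or self.horizon <= self.trial_period:
            raise ValidationError("horizon - trial_period must be a positive multiple of cycle_length")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        for name in ("cost_per_dose", "trial_background_cost"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.doses_per_course < 0:
            raise ValidationError("doses_per_course must be >= 0")
        if self.fd_change_rmse < 0:
            raise ValidationError("fd_change_rmse must be >= 0")
        if self.quiescence_duration <= 0:
            raise ValidationError("quiescence_duration must be positive")
        if self.late_stage_threshold <= 0:
            raise ValidationError("late_stage_threshold must be positive")
        for tag in self.provenance.values():
            if tag not in PROVENANCE_TAGS:
                raise ValidationError(f"unknown provenance tag {tag!r}")
        if self.late_stage is None or self.mortality is None:
            raise ValidationError("late_stage and mortality sub-records are required")
        self.late_stage.validate()
        self.mortality.validate()

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with scalar fields (or sub-record fields) replaced."""
        sub_ls = {k: v for k, v in changes.items() if hasattr(self.late_stage, k)}
        sub_mort = {
            k: v
            for k, v in changes.items()
            if hasattr(self.mortality, k) and k not in sub_ls
        }
        top = {k: v for k, v in changes.items() if k not in sub_ls and k not in sub_mort}
        if sub_ls:
            top["late_stage"] = dataclasses.replace(self.late_stage, **sub_ls)
        if sub_mort:
            top["mortality"] = dataclasses.replace(self.mortality, **sub_mort)
        return dataclasses.replace(self, **top)

    def config_hash(self) -> str:
        """Stable hash of every numeric input (for reproducibility metadata)."""
        import hashlib

        payload = {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name not in ("late_stage", "mortality", "uncertainty", "provenance")
        }
        payload["late_stage"] = dataclasses.asdict(self.late_stage)
        mort = dataclasses.asdict(self.mortality)
        lt = mort.pop("life_table", None)
        payload["mortality"] = mort
        if lt is not None and self.mortality.life_table is not None:
            payload["life_table"] = self.mortality.life_table.to_csv(index=False)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class ParameterDraws:
    """PSA parameter sample: one :class:`ModelParameters` realization per draw.

    ``table`` holds the sampled scalar values (one column per uncertain
    parameter) for value-of-information regressions.
    """

    base: ModelParameters
    n_draws: int
    seed: int
    table: pd.DataFrame
    realizations: tuple[ModelParameters, ...]

    def __len__(self) -> int:
        return self.n_draws


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = (
    "p_late_placebo",
    "p_quiescent_placebo",
    "p_late_ada",
    "p_quiescent_ada",
    "qaly_gain_quiescence",
    "qaly_reg_baseline_utility_coef",
    "qaly_reg_constant",
    "fd_change_constant",
    "fd_change_ectopic_coef",
    "fd_change_rmse",
    "quiescence_duration",
    "cycle_length",
    "horizon",
    "trial_period",
    "discount_rate",
    "late_stage_threshold",
    "cost_per_dose",
    "doses_per_course",
    "trial_background_cost",
    "uk_prevalent_cases",
    "wtp_grid",
)

_INT_FIELDS = {"doses_per_course", "uk_prevalent_cases"}


def _packaged_yaml(name: str) -> dict:
    text = resources.files("dupsim").joinpath("data", name).read_text()
    return yaml.safe_load(text)


def _read_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, Mapping):
        raise ConfigurationError(f"configuration file {path} does not hold a mapping")
    return dict(loaded)


def _entry(raw: Any, default_entry: Mapping[str, Any] | None, name: str) -> dict:
    """Normalize a config entry to {value, ci95?, range?, provenance}."""
    if isinstance(raw, Mapping):
        entry = dict(raw)
        if "value" not in entry:
            raise ConfigurationError(f"entry {name!r} has no 'value'")
    else:
        # bare scalar: inherit interval/provenance from the packaged default
        entry = dict(default_entry or {})
        entry["value"] = raw
    entry.setdefault("provenance", (default_entry or {}).get("provenance", "placeholder_literature"))
    return entry


def load_parameters(
    source: str | Path | Mapping[str, Any] | None = None,
    *,
    use_packaged_defaults: bool = True,
) -> ModelParameters:
    """Load and validate model parameters.

    ``source`` may be a YAML/JSON path or an in-memory mapping; entries it
    provides override the packaged defaults (the packaged
    ``late_stage_defaults.yaml`` placeholder file fills ``late_stage`` and
    ``mortality`` when omitted).  With ``use_packaged_defaults=False`` the
    source must be complete, and any missing field raises
    :class:`ConfigurationError` naming the field.
    """
    base = _packaged_yaml("default_parameters.yaml") if use_packaged_defaults else {}
    placeholder = _packaged_yaml("late_stage_defaults.yaml") if use_packaged_defaults else {}
    user = _read_config(source) if source is not None else {}

    known = set(_SCALAR_FIELDS) | {"late_stage", "mortality", "life_table"}
    unknown = set(user) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")

    values: dict[str, Any] = {}
    uncertainty: dict[str, dict] = {}
    provenance: dict[str, str] = {}

    for name in _SCALAR_FIELDS:
        default_entry = base.get(name)
        if name in user:
            entry = _entry(user[name], default_entry, name)
        elif default_entry is not None:
            entry = _entry(default_entry, None, name)
        else:
            raise ConfigurationError(f"missing required field: {name}")
        v = entry["value"]
        if name == "wtp_grid":
            values[name] = tuple(float(x) for x in v)
        elif name in _INT_FIELDS:
            values[name] = int(v)
        else:
            values[name] = float(v)
        provenance[name] = entry["provenance"]
        spec: dict[str, Any] = {}
        if "ci95" in entry and entry["ci95"] is not None:
            spec["ci95"] = tuple(float(x) for x in entry["ci95"])
        if "range" in entry and entry["range"] is not None:
            spec["range"] = tuple(float(x) for x in entry["range"])
        if spec:
            uncertainty[name] = spec

    # sub-records ------------------------------------------------------------
    for block_name, cls in (("late_stage", LateStageParams), ("mortality", MortalityParams)):
        block_default = placeholder.get(block_name, {})
        block_user = user.get(block_name, {}) or {}
        if not isinstance(block_user, Mapping):
            raise ConfigurationError(f"{block_name} must be a mapping")
        merged: dict[str, Any] = {}
        names = {f.name for f in dc_fields(cls)} - {"life_table"}
        for fname in names:
            default_entry = block_default.get(fname)
            if fname in block_user:
                entry = _entry(block_user[fname], default_entry, f"{block_name}.{fname}")
            elif default_entry is not None:
                entry = _entry(default_entry, None, f"{block_name}.{fname}")
            else:
                raise ConfigurationError(f"missing required field: {block_name}.{fname}")
            merged[fname] = float(entry["value"])
            provenance[f"{block_name}.{fname}"] = entry["provenance"]
            if "ci95" in entry and entry["ci95"] is not None:
                uncertainty[fname] = {"ci95": tuple(float(x) for x in entry["ci95"])}
        unknown = set(block_user) - names
        if unknown:
            raise ConfigurationError(f"unknown keys in {block_name}: {sorted(unknown)}")
        if block_name == "late_stage":
            late_stage = LateStageParams(**merged)
        else:
            life_table = None
            if "life_table" in user and user["life_table"]:
                life_table = pd.read_csv(user["life_table"])
            mortality = MortalityParams(**merged, life_table=life_table)

    return ModelParameters(
        **values,
        late_stage=late_stage,
        mortality=mortality,
        uncertainty=uncertainty,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# probabilistic sampling
# ---------------------------------------------------------------------------


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one master seed."""
    return np.random.SeedSequence(seed).spawn(n)


def _normal_sd(ci: tuple[float, float]) -> float:
    return (ci[1] - ci[0]) / _Z95


def _dirichlet_alpha(
    m_late: float, ci_late: tuple[float, float], m_q: float, ci_q: tuple[float, float]
) -> np.ndarray:
    """Dirichlet concentration matched to the two published interval widths.

    Each marginal of Dirichlet(alpha) is Beta with variance
    ``m (1 - m) / (s + 1)`` where ``s = sum(alpha)``; the implied ``s`` from
    each constrained category is averaged.
    """
    implied = []
    for m, ci in ((m_late, ci_late), (m_q, ci_q)):
        sd = _normal_sd(ci)
        implied.append(m * (1.0 - m) / sd**2 - 1.0)
    s = float(np.mean(implied))
    probs = np.array([m_late, m_q, 1.0 - m_late - m_q])
    return s * probs


def _beta_ab(mean: float, ci: tuple[float, float]) -> tuple[float, float]:
    sd = _normal_sd(ci)
    s = max(mean * (1.0 - mean) / sd**2 - 1.0, 1e-6)
    return mean * s, (1.0 - mean) * s


def _gamma_ks(mean: float, ci: tuple[float, float]) -> tuple[float, float]:
    sd = _normal_sd(ci)
    shape = (mean / sd) ** 2
    return shape, sd**2 / mean


def sample_psa(params: ModelParameters, n_draws: int, seed: int) -> ParameterDraws:
    """Sample ``n_draws`` parameter sets for probabilistic sensitivity analysis.

    Sampling is deterministic under a fixed ``(params, n_draws, seed)``
    triple.  Outcome probabilities are drawn jointly per arm so that
    ``p_late + p_quiescent <= 1`` holds in every realization.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    unc = params.uncertainty
    cols: dict[str, np.ndarray] = {}

    # jointly-sampled outcome probabilities, one Dirichlet per arm
    for arm in ("placebo", "ada"):
        m_late = getattr(params, f"p_late_{arm}")
        m_q = getattr(params, f"p_quiescent_{arm}")
        alpha = _dirichlet_alpha(
            m_late, unc[f"p_late_{arm}"]["ci95"], m_q, unc[f"p_quiescent_{arm}"]["ci95"]
        )
        draws = rng.dirichlet(alpha, size=n_draws)
        cols[f"p_late_{arm}"] = draws[:, 0]
        cols[f"p_quiescent_{arm}"] = draws[:, 1]

    # Normal regression coefficients
    for name in (
        "qaly_gain_quiescence",
        "qaly_reg_baseline_utility_coef",
        "qaly_reg_constant",
        "fd_change_constant",
        "fd_change_ectopic_coef",
    ):
        sd = _normal_sd(unc[name]["ci95"])
        cols[name] = rng.normal(getattr(params, name), sd, size=n_draws)

    # duration of quiescence: uniform over its sensitivity range
    lo, hi = unc["quiescence_duration"]["range"]
    cols["quiescence_duration"] = rng.uniform(lo, hi, size=n_draws)

    # placeholder late-stage inputs and the mortality hazard ratio
    ls = params.late_stage
    for fname in (f.name for f in dc_fields(LateStageParams)):
        if fname not in unc:
            continue
        mean = getattr(ls, fname)
        ci = unc[fname]["ci95"]
        if fname.startswith("cost_"):
            k, theta = _gamma_ks(mean, ci)
            cols[fname] = rng.gamma(k, theta, size=n_draws)
        else:
            a, b = _beta_ab(mean, ci)
            cols[fname] = rng.beta(a, b, size=n_draws)
    if "dd_hazard_ratio" in unc:
        hr = params.mortality.dd_hazard_ratio
        ci = unc["dd_hazard_ratio"]["ci95"]
        sigma = (np.log(ci[1]) - np.log(ci[0])) / _Z95
        cols["dd_hazard_ratio"] = rng.lognormal(np.log(hr) - sigma**2 / 2.0, sigma, size=n_draws)

    table = pd.DataFrame(cols)
    realizations = tuple(
        params.replace(**{k: float(table[k].iloc[i]) for k in table.columns})
        for i in range(n_draws)
    )
    return ParameterDraws(
        base=params, n_draws=n_draws, seed=seed, table=table, realizations=realizations
    )
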