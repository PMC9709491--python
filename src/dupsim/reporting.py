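"""Run orchestration: end-to-end analyses bundled into reproducible reports.

Each function is an importable, deterministic unit over the library; the
command-line interface is a thin wrapper around this module.  Run metadata
(seed, scale, config hash) is carried with every bundle so any number can be
reproduced bit-for-bit at the same scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import psa as psa_mod
from .cohort import CohortSpec, generate_cohort
from .economics import StrategyResult, incremental_analysis, strategy_table
from .params import RIDD_PARAMETERS, ModelParameters, load_parameters, sample_psa
from .psa import PSASamples, ceac, evpi_per_patient, evppi, population_value, run_psa
from .states import DEFAULT_STRATEGIES
from .within_trial import CUAResult, TrialSpec, bootstrap_cua, generate_trial_dataset

__all__ = ["ReportBundle", "SCALES", "parse_scale", "run_base_case", "run_within_trial"]

#: preset PSA scales: (n_draws, n_reps)
SCALES: Mapping[str, tuple[int, int]] = {
    "smoke": (2, 1),
    "desk": (200, 20),
    "paper": (1000, 100),
}


def parse_scale(scale: str) -> tuple[int, int]:
    """A preset name ('smoke', 'desk', 'paper') or an explicit 'DRAWSxREPS'."""
    if scale in SCALES:
        return SCALES[scale]
    try:
        d, r = scale.lower().split("x")
        return int(d), int(r)
    except ValueError:
        raise ValueError(f"unrecognized scale {scale!r}; use a preset or 'DRAWSxREPS'") from None


@dataclass
class ReportBundle:
    """Everything the base-case analysis produces, plus reproducibility metadata."""

    strategy_results: list[StrategyResult]
    incremental: pd.DataFrame
    ceac: pd.DataFrame
    voi: pd.DataFrame  # per WTP: EVPI / EVPPI per patient and population
    samples: PSASamples
    metadata: dict
    tornado: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        return strategy_table(self.strategy_results)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(out / "strategy_results.csv")
        self.incremental.to_csv(out / "incremental.csv", index=False)
        self.ceac.to_csv(out / "ceac.csv", index=False)
        self.voi.to_csv(out / "voi.csv", index=False)
        psa_mod.write_psa(self.samples, out / "psa.csv")
        if self.samples.param_table is not None:
            self.samples.param_table.to_csv(out / "psa_params.csv", index=False)
        if self.tornado is not None:
            self.tornado.to_csv(out / "tornado.csv", index=False)
        (out / "run_summary.json").write_text(json.dumps(self.metadata, indent=2, default=float))


def _strategy_results_from_psa(samples: PSASamples) -> list[StrategyResult]:
    """Collapse PSA draws into per-strategy means with percentile intervals."""
    results = []
    ex = samples.extras
    for j, name in enumerate(samples.strategies):
        fields = {
            "qalys_trial": ex["qalys_trial"][:, j],
            "qalys_model": ex["qalys_model"][:, j],
            "costs_trial": ex["cost_trial"][:, j],
            "costs_model": ex["cost_model"][:, j],
            "life_expectancy": ex["life_expectancy"][:, j],
            "years_early_stage": ex["years_early"][:, j],
            "years_free_late_stage": ex["years_free_late"][:, j],
            "n_courses": ex["courses"][:, j],
            "n_operations": ex["operations"][:, j],
        }
        ci = {
            k: tuple(np.percentile(v, [2.5, 97.5]))
            for k, v in {**fields, "qalys_lifetime": samples.qalys[:, j], "costs_lifetime": samples.costs[:, j]}.items()
        }
        results.append(
            StrategyResult(
                strategy=name,
                **{k: float(np.mean(v)) for k, v in fields.items()},
                ci=ci,
            )
        )
    return results


def run_base_case(
    config_path: str | Path | None = None,
    scale: str = "desk",
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    with_tornado: bool = False,
    tornado_reps: int = 50,
) -> ReportBundle:
    """Full pipeline: cohort -> PSA -> incremental analysis -> CEAC -> VoI.

    ``scale`` sets (PSA draws, repetitions per patient); 'paper' is
    1000 x 100.  All randomness derives from ``seed`` through independent
    streams for parameter sampling, cohort generation and simulation.
    """
    params = load_parameters(config_path)
    n_draws, n_reps = parse_scale(scale)
    seed_psa, seed_cohort, seed_sim, seed_tornado = [
        int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    cohort = generate_cohort(cohort_spec, seed=seed_cohort)
    draws = sample_psa(params, n_draws, seed=seed_psa)
    samples = run_psa(cohort, draws, DEFAULT_STRATEGIES, n_reps=n_reps, seed=seed_sim)

    results = _strategy_results_from_psa(samples)
    means = {
        name: (float(samples.costs[:, j].mean()), float(samples.qalys[:, j].mean()))
        for j, name in enumerate(samples.strategies)
    }
    incremental = incremental_analysis(means)
    curves = ceac(samples, params.wtp_grid)

    voi_rows = []
    for wtp in (20000.0, 30000.0):
        evpi = evpi_per_patient(samples, wtp)
        evppi_ridd = (
            evppi_val
            if (evppi_val := _safe_evppi(samples, wtp)) is not None
            else float("nan")
        )
        voi_rows.append(
            {
                "wtp": wtp,
                "evpi_per_patient": evpi,
                "evpi_population": population_value(evpi, params.uk_prevalent_cases),
                "evppi_ridd_per_patient": evppi_ridd,
                "evppi_ridd_population": population_value(max(evppi_ridd, 0.0), params.uk_prevalent_cases)
                if np.isfinite(evppi_ridd)
                else float("nan"),
            }
        )
    voi = pd.DataFrame(voi_rows)

    tornado = None
    if with_tornado:
        tornado = psa_mod.one_way_sa(params, cohort, n_reps=tornado_reps, seed=seed_tornado)

    metadata = {
        "seed": seed,
        "scale": scale,
        "n_draws": n_draws,
        "n_reps": n_reps,
        "cohort_n": len(cohort),
        "config_hash": params.config_hash(),
        "strategies": list(samples.strategies),
        "parameter_provenance": dict(params.provenance),
    }
    return ReportBundle(
        strategy_results=results,
        incremental=incremental,
        ceac=curves,
        voi=voi,
        samples=samples,
        metadata=metadata,
        tornado=tornado,
    )


def _safe_evppi(samples: PSASamples, wtp: float) -> float | None:
    # the regression estimator needs a handful of draws to be meaningful
    if samples.n_draws < 20:
        return None
    return evppi(samples, RIDD_PARAMETERS, wtp)


def run_within_trial(
    trial_spec: TrialSpec | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
) -> tuple[CUAResult, pd.DataFrame, dict]:
    """Within-trial CUA end-to-end: generate data, bootstrap, summarize.

    Returns ``(result, dataset, metadata)``.
    """
    seed_data, seed_boot = [
        int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    dataset = generate_trial_dataset(trial_spec, seed=seed_data)
    result = bootstrap_cua(dataset, n_boot=n_boot, wtp_grid=wtp_grid, seed=seed_boot)
    metadata = {"seed": seed, "n_boot": n_boot, "n_participants": len(dataset)}
    return result, dataset, metadata
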