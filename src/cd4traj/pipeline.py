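"""End-to-end pipeline: load -> filter -> split -> select -> fit -> predict
-> crossing -> (bootstrap) -> KM, with a machine-readable run manifest.

Each stage writes plain CSV/JSON artifacts into the output directory; the
manifest records the configuration, seeds and per-stage outputs so a run
can be reproduced bit-identically (seed-identically for stochastic
stages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortData,
    apply_inclusion_filters,
    load_cohort,
    person_time_summary,
    split_periods,
)
from .crossing import Threshold, bootstrap_crossing_ci, crossing_table, sorted_crossing_probabilities
from .fp import POWER_GRID, FPSpec
from .lmm import fit_fp_lmm, select_fp_model
from .prediction import prediction_report
from .simulate import default_cohort_config, simulate_cohort
from .survival import compare_groups

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Defaults follow the study design: estimation window 0--30 months,
    thresholds 200/350/500 cells/mm^3, FP1+FP2 candidates over the
    conventional power grid, 1000 bootstrap replicates.
    """

    input: str | None = None  # CSV path; None -> simulate
    outdir: str = "cd4traj_run"
    cutoff: float = 30.0
    sensitivity_cutoffs: tuple[float, ...] = ()
    thresholds: tuple[float, ...] = (200.0, 350.0, 500.0)
    orders: tuple[int, ...] = (1, 2)
    grid: tuple[float, ...] = tuple(POWER_GRID)
    time_offset: float = 1.0
    random_structure: str = "all"
    scan_random_structure: str | None = None
    horizon: float = 120.0
    spacing: float = 1.0
    prob_times: tuple[float, ...] = (60.0, 90.0, 120.0)
    bootstrap_reps: int = 1000
    bootstrap_patients: tuple[str, ...] = ()  # empty -> no bootstrap stage
    seed: int = 0
    simulate_n: tuple[int, int] = (1100, 247)  # (NVP, EFV) when simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("thresholds", "orders", "grid", "prob_times", "bootstrap_patients",
                    "sensitivity_cutoffs", "simulate_n"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure aborts with a stage-labelled error message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "load"
    try:
        if config.input is None:
            sim = default_cohort_config(*config.simulate_n, seed=config.seed)
            cohort, _truth = simulate_cohort(sim)
            cohort.write_csv(out / "simulated_cohort.csv")
            manifest["stages"]["load"] = {"source": "simulated", "seed": config.seed}
        else:
            cohort = load_cohort(config.input)
            manifest["stages"]["load"] = {"source": config.input}

        stage = "filter"
        cohort = apply_inclusion_filters(cohort)
        _write_json(out / "filter_report.json", cohort.filter_report())
        _write_json(out / "person_time.json", person_time_summary(cohort))
        manifest["stages"]["filter"] = cohort.filter_report()

        stage = "split"
        est, pred = split_periods(cohort, config.cutoff)
        manifest["stages"]["split"] = {
            "cutoff": config.cutoff,
            "n_estimation_visits": est.n_visits,
            "n_prediction_visits": pred.n_visits,
        }

        stage = "select+fit"
        models: dict[str, object] = {}
        aic_tables = []
        # powers are selected on the full follow-up, then the chosen
        # structure is refit on the estimation window only
        est_groups = est.by_regimen()
        for name, sub_full in cohort.by_regimen().items():
            sub_est = est_groups[name]
            best, table = select_fp_model(
                sub_full,
                orders=config.orders,
                grid=config.grid,
                time_offset=config.time_offset,
                random_structure=config.scan_random_structure or config.random_structure,
            )
            table.insert(0, "group", name)
            aic_tables.append(table)
            spec = best.with_random_structure(config.random_structure)
            model = fit_fp_lmm(sub_est, spec, method="reml")
            model.window_ = (0.0, config.cutoff)
            models[name] = model
            _write_json(out / f"model_{name}.json", model.to_dict())
            model.ranef_frame().to_csv(out / f"ranef_{name}.csv")
        pd.concat(aic_tables).to_csv(out / "aic_table.csv", index=False)
        manifest["stages"]["select+fit"] = {
            name: {"powers": list(m.spec_.powers), "aic": m.aic_, "converged": m.converged_}
            for name, m in models.items()
        }

        stage = "predict"
        correlations = {}
        cutoffs = [config.cutoff, *config.sensitivity_cutoffs]
        for co in cutoffs:
            for name, sub in cohort.by_regimen().items():
                sub_est, _ = split_periods(sub, co)
                m = models[name] if co == config.cutoff else fit_fp_lmm(
                    sub_est, models[name].spec_, method="reml"
                )
                rep = prediction_report(m, sub, cutoff=co)
                tag = f"{name}_cutoff{co:g}"
                rep.write_csv(out / f"predictions_{tag}.csv")
                correlations[tag] = rep.correlations
        _write_json(out / "correlations.json", correlations)
        manifest["stages"]["predict"] = correlations

        stage = "crossing"
        crossing_rows = []
        for name, model in models.items():
            sub = cohort.by_regimen()[name]
            tab = crossing_table(
                model, sub.patient_ids, config.thresholds, config.horizon, config.spacing
            )
            tab.insert(0, "group", name)
            crossing_rows.append(tab)
            for t_eval in config.prob_times:
                sp = sorted_crossing_probabilities(
                    model, sub, Threshold.from_cd4(350), t_eval, config.spacing
                )
                pd.DataFrame(
                    {"patient_id": sp["patient_ids"], "probability": sp["probabilities"]}
                ).to_csv(out / f"sorted_probs_{name}_t{t_eval:g}.csv", index=False)
        pd.concat(crossing_rows).to_csv(out / "crossing_table.csv", index=False)
        manifest["stages"]["crossing"] = {
            "thresholds": list(config.thresholds),
            "horizon": config.horizon,
        }

        if config.bootstrap_patients:
            stage = "bootstrap"
            cis = {}
            for pid in config.bootstrap_patients:
                grp = str(cohort.covariates.loc[pid, "regimen"])
                sub = cohort.by_regimen()[grp]
                sub_est, _ = split_periods(sub, config.cutoff)
                ci = bootstrap_crossing_ci(
                    sub_est,
                    pid,
                    Threshold.from_cd4(350),
                    spec=models[grp].spec_,
                    B=config.bootstrap_reps,
                    seed=config.seed,
                    horizon=config.horizon,
                    spacing=config.spacing,
                )
                cis[str(pid)] = ci.to_dict()
            _write_json(out / "bootstrap_cis.json", cis)
            manifest["stages"]["bootstrap"] = cis

        stage = "km"
        km_out = {}
        for cd4 in config.thresholds:
            th = Threshold.from_cd4(cd4)
            cmp = compare_groups(cohort, th)
            entry: dict = {}
            for name, estim in cmp["groups"].items():
                estim.curve.to_csv(out / f"km_{name}_cd4_{cd4:g}.csv", index=False)
                entry[name] = {
                    "median": estim.median,
                    "median_ci": list(estim.median_ci),
                    "n": int(len(estim.times)),
                    "events": int(estim.events.sum()),
                }
            if "logrank" in cmp:
                entry["logrank"] = cmp["logrank"]
            km_out[f"cd4_{cd4:g}"] = entry
        _write_json(out / "km_summary.json", km_out)
        manifest["stages"]["km"] = km_out
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    _write_json(out / "manifest.json", manifest)
    logger.info("pipeline complete; artifacts in %s", out)
    return manifest
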