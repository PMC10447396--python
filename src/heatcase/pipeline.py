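"""One-command orchestration: simulate -> clean -> link -> strata -> fit ->
subgroups -> trend, with logging, stable output schemas and a manifest that
suffices to re-run the identical analysis.

All randomness flows from ``RunConfig.seed``: the simulation seed and the
per-stage seeds (linkage fuzzing, trend draws) are split from it with a
``SeedSequence`` and recorded in the manifest.  Under the default Laplace
backend a re-run with the same config is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import HeatcaseError
from .synthetic import (
    SimulationConfig,
    SyntheticStudy,
    config_from_dict,
    load_study,
    simulate_study,
    _yamlable,
)
from .linkage import apply_exclusions, link_records
from .design import build_strata
from .inference import ModelSpec, fit_model, linearity_summary
from .design import build_design_matrix
from .modification import subgroup_fit, subgroup_table, trend_by_age

logger = logging.getLogger(__name__)

TREND_COLUMNS = ["age_group", "slope_median", "slope_lo", "slope_hi", "n_years"]


@dataclass
class RunConfig:
    """Everything one analysis run needs (YAML-serializable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # ingest a saved study instead of simulating
    lag_set: tuple = (0, 1, 2, 3)
    models: tuple = ("unadjusted", "adjusted")
    rw2: bool = False
    lag_sweep: bool = False
    partitions: tuple = (("sex", "age_group"),)
    trend: bool = False
    n_draws: int = 1000
    min_events: int = 50
    fuzz_radius: float = 0.1
    prior_sd: float = 10.0
    patient_effect: bool = True
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return _yamlable(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = config_from_dict(d["simulation"])
        for key in ("lag_set", "models"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "partitions" in d:
            d["partitions"] = tuple(tuple(p) for p in d["partitions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_fit(fit, name: str, outdir: Path, artifacts: list) -> None:
    coefs = fit.coef.reset_index()
    path = outdir / f"fit_{name}_coefficients.csv"
    coefs.to_csv(path, index=False)
    artifacts.append(path.name)
    summary = {
        "model": name,
        "percent_change_per_degC": fit.percent_change,
        "diagnostics": {
            k: v for k, v in fit.diagnostics.items() if _jsonable(v)
        },
    }
    jpath = outdir / f"fit_{name}.json"
    jpath.write_text(json.dumps(summary, indent=2, default=_coerce))
    artifacts.append(jpath.name)


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, list, dict, type(None), np.floating, np.integer))


def _coerce(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    raise TypeError(f"not JSON-serializable: {type(v)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the output manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    seq = np.random.SeedSequence(config.seed)
    link_seed, trend_seed = (int(s) for s in seq.generate_state(2) % (2**31))

    def stage(name):
        logger.info("stage: %s", name)

    try:
        if config.input_dir is not None:
            stage("ingest")
            study: SyntheticStudy = load_study(config.input_dir)
            logger.info("loaded %d records from %s",
                        len(study.records), config.input_dir)
        else:
            stage("simulate")
            study = simulate_study(config.simulation)
            logger.info("simulated %d records (%d injected defects)",
                        len(study.records), config.simulation.noise.total)

        stage("exclusions")
        retained, report = apply_exclusions(study.records, study.temperature)
        logger.info("\n%s", report)
        (outdir / "exclusion_report.json").write_text(report.to_json(indent=2))
        artifacts.append("exclusion_report.json")

        stage("linkage")
        linked = link_records(
            retained, study.temperature, study.covariates, study.holidays,
            lag_set=config.lag_set, fuzz_radius=config.fuzz_radius,
            seed=link_seed,
        )

        stage("strata")
        strata = build_strata(
            linked, study.temperature, study.covariates, study.holidays,
            lag_set=config.lag_set,
        )
        logger.info("%d strata, %d stratum-days",
                    strata["stratum_id"].nunique(), len(strata))

        stage("fit")
        fits = {}
        for name in config.models:
            spec = ModelSpec(adjusted=(name == "adjusted"),
                             prior_sd=config.prior_sd,
                             patient_effect=config.patient_effect)
            design = build_design_matrix(strata, adjusted=spec.adjusted)
            fits[name] = fit_model(design, spec)
            _write_fit(fits[name], name, outdir, artifacts)
            logger.info("%s: %% change per degC = %.3f (%.3f, %.3f)", name,
                        *(fits[name].percent_change[k] for k in ("median", "lo", "hi")))

        if config.rw2:
            stage("rw2")
            spec = ModelSpec(temperature="rw2", adjusted=True,
                             prior_sd=config.prior_sd)
            design = build_design_matrix(strata, adjusted=True)
            rw2_fit = fit_model(design, spec)
            rw2_fit.curve.to_csv(outdir / "rw2_curve.csv", index=False)
            artifacts.append("rw2_curve.csv")
            lin = linearity_summary(rw2_fit)
            (outdir / "rw2_linearity.json").write_text(json.dumps(lin, indent=2))
            artifacts.append("rw2_linearity.json")

        if config.lag_sweep:
            stage("lag_sweep")
            rows = []
            for max_lag in range(6):
                lags = tuple(range(max_lag + 1))
                linked_l = link_records(
                    retained, study.temperature, study.covariates,
                    study.holidays, lag_set=lags,
                    fuzz_radius=config.fuzz_radius, seed=link_seed,
                )
                strata_l = build_strata(
                    linked_l, study.temperature, study.covariates,
                    study.holidays, lag_set=lags,
                )
                design_l = build_design_matrix(strata_l, adjusted=True)
                f = fit_model(design_l, ModelSpec(adjusted=True,
                                                  prior_sd=config.prior_sd))
                rows.append({"lags": f"0-{max_lag}" if max_lag else "0",
                             **{f"pct_{k}": v
                                for k, v in f.percent_change.items()}})
            pd.DataFrame(rows).to_csv(outdir / "lag_sweep.csv", index=False)
            artifacts.append("lag_sweep.csv")

        stage("subgroups")
        subgroup_frames = {}
        for partition in config.partitions:
            spec = ModelSpec(adjusted=True, prior_sd=config.prior_sd)
            res = subgroup_fit(strata, list(partition), spec,
                               min_events=config.min_events)
            tab = subgroup_table(res)
            key = "_".join(partition)
            subgroup_frames[key] = tab
            path = outdir / f"subgroups_{key}.csv"
            tab.to_csv(path, index=False)
            artifacts.append(path.name)

        trend_frames = None
        if config.trend:
            stage("trend")
            spec = ModelSpec(adjusted=True, prior_sd=config.prior_sd)
            trends = trend_by_age(strata, spec, n_draws=config.n_draws,
                                  seed=trend_seed, min_events=config.min_events)
            rows, yearly = [], []
            for label, tr in trends.items():
                rows.append({"age_group": label,
                             "slope_median": tr.slope_median,
                             "slope_lo": tr.slope_lo,
                             "slope_hi": tr.slope_hi,
                             "n_years": len(tr.years)})
                py = tr.per_year.copy()
                py.insert(0, "age_group", label)
                yearly.append(py)
            trend_frames = pd.DataFrame(rows, columns=TREND_COLUMNS)
            trend_frames.to_csv(outdir / "trend_slopes.csv", index=False)
            artifacts.append("trend_slopes.csv")
            pd.concat(yearly, ignore_index=True).to_csv(
                outdir / "trend_yearly_effects.csv", index=False)
            artifacts.append("trend_yearly_effects.csv")

    except HeatcaseError:
        logger.exception("pipeline stage failed")
        raise

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {"root": config.seed, "linkage": link_seed,
                  "trend": trend_seed,
                  "simulation": config.simulation.seed},
        "n_records_input": int(report.n_input),
        "n_records_retained": int(report.n_retained),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_tables(subgroup_results: list, outdir, name: str = "effects") -> Path:
    """Write a tidy subgroup-effects table (header-only when empty)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tab = subgroup_table(subgroup_results)
    if tab.empty:
        tab = pd.DataFrame(
            columns=["n_events", "pct_median", "pct_lo", "pct_hi", "skipped"]
        )
    path = outdir / f"{name}.csv"
    tab.to_csv(path, index=False)
    return path
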