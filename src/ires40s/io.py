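"""File formats, analysis configuration and the end-to-end pipeline.

Time courses travel as delimited text with columns
``experiment_id, mode, time_min, frac_bound, sigma`` (sigma optional);
experiment designs and analysis settings live in YAML.  The pipeline
reproduces the fitting workflow: biphasic pre-fits, rule-based parameter
initialization, global fit, profile confidence bounds and optionally a
model comparison — emitting a JSON-serializable results document that is
byte-identical for identical config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import units
from .estimation import (
    compare_models,
    fit_biphasic,
    fit_pipeline,
    profile_confidence,
)
from .reaction_model import (
    DEFAULT_TEMPERATURE_K,
    ExperimentDesign,
    RateConstants,
    TimeCourse,
)
from .synthetic_data import VARIANTS
from .thermodynamics import STANDARD_CONC_M, build_landscape

__all__ = [
    "AnalysisConfig",
    "read_timecourses",
    "write_timecourses",
    "read_design_config",
    "write_design_config",
    "run_pipeline",
]

_REQUIRED_COLUMNS = ("experiment_id", "mode", "time_min", "frac_bound")


def write_timecourses(timecourses: list[TimeCourse], path: str | Path) -> None:
    """Serialize time courses to tab-delimited text."""
    rows = []
    for tc in timecourses:
        sig = tc.sigma if tc.sigma is not None else np.full(len(tc), np.nan)
        for t, y, s in zip(tc.times, tc.frac_bound, sig):
            rows.append({
                "experiment_id": tc.design.experiment_id,
                "mode": tc.design.mode,
                "time_min": t,
                "frac_bound": y,
                "sigma": s,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timecourses(
    path: str | Path, designs: dict[str, ExperimentDesign]
) -> list[TimeCourse]:
    """Parse and validate a delimited time-course table.

    Rows are grouped by experiment_id and attached to the matching design
    from the config.  Duplicate (experiment_id, time) pairs, unknown
    experiments and physically absurd fractions are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.duplicated(subset=["experiment_id", "time_min"]).any():
        raise ValueError(f"{path}: duplicate (experiment_id, time_min) rows")
    bad = df[(df["frac_bound"] < -0.2) | (df["frac_bound"] > 1.2)]
    if len(bad):
        raise ValueError(
            f"{path}: frac_bound outside [-0.2, 1.2] at rows {bad.index.tolist()}"
        )
    out = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        if exp_id not in designs:
            raise ValueError(f"{path}: no design configured for experiment {exp_id!r}")
        design = designs[exp_id]
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: non-increasing times in experiment {exp_id!r}")
        sigma = None
        if "sigma" in grp.columns and grp["sigma"].notna().all():
            sigma = grp["sigma"].to_numpy(dtype=float)
        out.append(TimeCourse(
            design=design,
            times=times,
            frac_bound=grp["frac_bound"].to_numpy(dtype=float),
            sigma=sigma,
        ))
    return out


def write_design_config(designs: list[ExperimentDesign], path: str | Path) -> None:
    doc = {"experiments": {}}
    for d in designs:
        entry = {
            "mode": d.mode,
            "conc_40S_total_nM": d.conc_40S_total,
            "conc_IRES_labeled_nM": d.conc_IRES_labeled,
            "timepoints_min": [float(t) for t in d.timepoints],
            "temperature_K": d.temperature,
        }
        if d.mode == "chase":
            entry["preincubation_min"] = d.preincubation
            entry["conc_competitor_nM"] = d.conc_competitor
        doc["experiments"][d.experiment_id] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_design_config(path: str | Path) -> dict[str, ExperimentDesign]:
    doc = yaml.safe_load(Path(path).read_text())
    designs = {}
    for exp_id, e in doc["experiments"].items():
        designs[exp_id] = ExperimentDesign(
            mode=e["mode"],
            conc_40S_total=e["conc_40S_total_nM"],
            conc_IRES_labeled=e["conc_IRES_labeled_nM"],
            timepoints=tuple(e["timepoints_min"]),
            preincubation=e.get("preincubation_min"),
            conc_competitor=e.get("conc_competitor_nM"),
            temperature=e.get("temperature_K", DEFAULT_TEMPERATURE_K),
            experiment_id=exp_id,
        )
    return designs


@dataclass
class AnalysisConfig:
    """Settings of one full analysis run."""

    data_paths: list[str]
    design_path: str
    scheme_ids: list[str] = field(default_factory=lambda: ["two_step_reversible"])
    weighting: str = "auto"
    level: float = 0.95
    temperature: float = DEFAULT_TEMPERATURE_K
    std_conc: float = STANDARD_CONC_M
    seed: int = 0
    outdir: str = "."
    max_rounds: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must be in (0, 1)")
        if not self.scheme_ids:
            raise ValueError("at least one scheme_id is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _params_both_units(params: dict[str, float]) -> dict[str, dict[str, float]]:
    """Report parameters in internal (nM, min) and SI-style units."""
    out = {}
    for name, v in params.items():
        if name == "k1" or name.startswith("k1"):
            out[name] = {
                "nM^-1.min^-1": v,
                "uM^-1.s^-1": units.second_order_per_uM_s(v),
            }
        elif name.startswith("k"):
            out[name] = {"min^-1": v, "s^-1": units.first_order_per_s(v)}
        else:
            out[name] = {"dimensionless": v}
    return out


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and return the results document.

    Stages: load -> biphasic pre-fits -> initialization -> global fit of
    the primary scheme -> profile confidence bounds -> model comparison
    (when several schemes are configured).  Deterministic for identical
    config; every stage's settings are embedded in the document.
    """
    stage = "load"
    try:
        designs = read_design_config(config.design_path)
        datasets: list[TimeCourse] = []
        for p in config.data_paths:
            datasets.extend(read_timecourses(p, designs))

        stage = "biphasic_prefit"
        prefits = {}
        for tc in datasets:
            key = tc.design.experiment_id
            if key not in prefits:
                f = fit_biphasic(tc)
                prefits[key] = {"a1": f.a1, "b1": f.b1, "a2": f.a2,
                                "b2": f.b2, "c": f.c, "rss": f.rss}

        stage = "global_fit"
        primary = config.scheme_ids[0]
        result, init = fit_pipeline(
            datasets, primary, weighting=config.weighting,
            max_rounds=config.max_rounds,
        )

        stage = "confidence"
        bounds = profile_confidence(datasets, result, level=config.level)

        comparison = None
        if len(config.scheme_ids) > 1:
            stage = "model_comparison"
            comparison = compare_models(
                datasets, config.scheme_ids, init, weighting=config.weighting
            )

        stage = "landscape"
        landscape = None
        if primary == "two_step_reversible":
            ls = build_landscape(
                {"fit": result.rates}, T=config.temperature,
                std_conc=config.std_conc,
            )
            landscape = {
                "states": list(ls.states),
                "energies_J_per_mol": {k: v.tolist() for k, v in ls.energies.items()},
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    doc = {
        "config": {
            "data_paths": list(config.data_paths),
            "design_path": config.design_path,
            "scheme_ids": list(config.scheme_ids),
            "weighting": config.weighting,
            "level": config.level,
            "temperature_K": config.temperature,
            "std_conc_M": config.std_conc,
            "seed": config.seed,
            "max_rounds": config.max_rounds,
        },
        "n_datasets": len(datasets),
        "n_points": result.n_points,
        "biphasic_prefits": prefits,
        "fit": {
            "scheme_id": result.scheme_id,
            "parameters": _params_both_units(result.params),
            "chi2": result.chi2,
            "ssr": result.ssr,
            "n_iterations": result.n_iterations,
            "converged": result.converged,
        },
        "confidence": {
            "level": bounds.level,
            "bounds": {k: list(v) for k, v in bounds.bounds.items()},
            "open_bounds": {k: list(v) for k, v in bounds.open_bounds.items()},
        },
        "model_comparison": (
            [{k: row[k] for k in
              ("scheme_id", "chi2", "ssr", "n_params", "aicc", "converged", "rank")}
             for row in comparison.table] if comparison else None
        ),
        "landscape": landscape,
        "fixture_provenance": {
            name: VARIANTS[name].provenance for name in sorted(VARIANTS)
        },
    }
    return doc


def write_results(doc: dict, path: str | Path) -> None:
    """Write a results document as deterministic, sorted JSON."""
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=float))
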