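"""End-to-end pipeline: simulate/load -> indicators -> adjustment ->
profiling -> funnels -> composite, with a run manifest and a readable
report. All stage outputs are plain CSV so every number in the report can
be traced back to a file."""
from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .casemix import adjusted_contrasts
from .composite import build_composite
from .config import (INDICATOR_NAMES, PipelineConfig, config_to_dict)
from .errors import DataIntegrityError
from .funnel import build_curves, place_facilities, render_funnels
from .indicators import aggregate, compute_failure_flags
from .profiling import profile_indicators
from .simulate import simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

_SCHEMAS = {
    "facilities": ["facility_id", "department", "category",
                   "travel_time_minutes", "slope"],
    "patients": ["patient_id", "facility_id", "age_at_diagnosis", "gender",
                 "marital_status", "pregnant_at_art_start", "bmi",
                 "who_stage", "hiv_diagnosis_date", "art_start_date",
                 "year_art_start"],
    "dispenses": ["patient_id", "pickup_date", "days_supplied",
                  "multi_month", "stable"],
    "labs": ["patient_id", "test_date"],
}


def validate_tables(tables: dict) -> None:
    """Schema check for the four input tables; raises with a per-column
    report on failure."""
    problems = []
    for name, required in _SCHEMAS.items():
        if name not in tables:
            problems.append(f"{name}: table missing")
            continue
        missing = [c for c in required if c not in tables[name].columns]
        problems.extend(f"{name}: missing column {c}" for c in missing)
    if "patients" in tables and "patient_id" in tables["patients"]:
        if tables["patients"]["patient_id"].duplicated().any():
            problems.append("patients: duplicate patient_id values")
    if problems:
        raise DataIntegrityError("input validation failed:\n  "
                                 + "\n  ".join(problems))


def load_tables(indir: str) -> dict:
    tables = {}
    for name in ("facilities", "patients", "dispenses", "labs"):
        path = os.path.join(indir, f"{name}.csv")
        if not os.path.exists(path):
            raise DataIntegrityError(f"missing input file: {path}")
        tables[name] = pd.read_csv(path, keep_default_na=True,
                                   dtype={"art_start_date": str}
                                   if name == "patients" else None)
    if "art_start_date" in tables["patients"]:
        tables["patients"]["art_start_date"] = \
            tables["patients"]["art_start_date"].fillna("")
    validate_tables(tables)
    return tables


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None,
                 plots: bool = False) -> dict:
    """Execute every stage and return the output bundle as a dict of
    DataFrames (written to ``outdir`` as CSV when given)."""
    cfg = cfg.resolved()
    cfg.validate()

    if cfg.input_dir:
        tables = load_tables(cfg.input_dir)
        roster, patients = tables["facilities"], tables["patients"]
        dispenses, labs = tables["dispenses"], tables["labs"]
        truth = None
    else:
        roster, patients, dispenses, labs, truth = simulate_dataset(
            cfg.simulate)
    logger.info("inputs: %d facilities, %d patients, %d dispense events, "
                "%d lab events", len(roster), len(patients), len(dispenses),
                len(labs))

    flags = compute_failure_flags(patients, dispenses, labs, cfg.indicators)
    aggregates, pi0 = aggregate(flags, roster)
    logger.info("indicators: %d unit flags aggregated", len(flags))

    contrasts, models = adjusted_contrasts(
        flags, patients, roster, ridge_alpha=cfg.profiling.ridge_alpha)
    profile = profile_indicators(aggregates, pi0, contrasts, cfg.profiling)
    logger.info("profiling: %d facility tests, %d flags", len(profile),
                int((profile["flag"] != "none").sum()))

    curves = build_curves(profile, pi0, aggregates, contrasts,
                          alpha=cfg.profiling.alpha)
    placed = place_facilities(profile, pi0, aggregates, contrasts,
                              alpha=cfg.profiling.alpha)
    composite = build_composite(profile, cfg.composite)

    bundle = {
        "roster": roster, "patients": patients, "dispenses": dispenses,
        "labs": labs, "truth": truth, "flags": flags,
        "aggregates": aggregates, "pi0": pi0, "contrasts": contrasts,
        "models": models, "profile": profile, "curves": curves,
        "placed": placed, "composite": composite, "config": cfg,
    }

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        if truth is not None:
            write_dataset(outdir, roster, patients, dispenses, labs, truth)
        aggregates.to_csv(os.path.join(outdir, "indicator_aggregates.csv"),
                          index=False)
        pi0.to_frame().reset_index().to_csv(
            os.path.join(outdir, "pi0.csv"), index=False)
        contrasts.to_csv(os.path.join(outdir, "casemix_contrasts.csv"),
                         index=False)
        for k, model in models.items():
            model.params.rename_axis("term").rename("coefficient") \
                .to_csv(os.path.join(outdir,
                                     f"casemix_coefficients_{k}.csv"))
        profile.to_csv(os.path.join(outdir, "profiling.csv"), index=False)
        curves.to_csv(os.path.join(outdir, "funnel_curves.csv"), index=False)
        placed.to_csv(os.path.join(outdir, "funnel_facilities.csv"),
                      index=False)
        composite.to_csv(os.path.join(outdir, "composite.csv"), index=False)
        manifest = build_manifest(cfg, bundle)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(os.path.join(outdir, "report.md"), "w") as fh:
            fh.write(render_report(bundle))
        if plots:
            render_funnels(curves, placed, os.path.join(outdir, "figures"))
    return bundle


def build_manifest(cfg: PipelineConfig, bundle: dict) -> dict:
    import scipy
    import statsmodels
    return {
        "config_hash": _config_hash(cfg),
        "seed": cfg.simulate.seed,
        "versions": {
            "qocprofile": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "row_counts": {
            name: int(len(bundle[name]))
            for name in ("roster", "patients", "dispenses", "labs", "flags",
                         "aggregates", "contrasts", "profile", "composite")
            if bundle.get(name) is not None
        },
        "n_flagged": int((bundle["profile"]["flag"] != "none").sum()),
        "config": config_to_dict(cfg),
    }


def render_report(bundle: dict) -> str:
    """Human-readable markdown report of flagged facilities and the
    composite ranking."""
    profile, composite = bundle["profile"], bundle["composite"]
    cfg: PipelineConfig = bundle["config"]
    lines = ["# Facility performance profiling report", ""]
    lines.append(f"- facilities: {len(bundle['roster'])}")
    lines.append(f"- over-dispersion method: {cfg.profiling.method}")
    lines.append(f"- alpha: {cfg.profiling.alpha} (Bonferroni-corrected "
                 "per indicator)")
    lines.append("")

    lines.append("## Per-indicator outliers")
    any_flag = False
    for k, name in INDICATOR_NAMES.items():
        sub = profile[(profile["indicator"] == k)
                      & (profile["flag"] != "none")]
        lines.append(f"\n### Indicator {k}: {name}")
        if sub.empty:
            lines.append("no outliers detected")
            continue
        any_flag = True
        for _, r in sub.sort_values("p_value").iterrows():
            direction = ("more failure" if r["direction"] > 0
                         else "less failure")
            lines.append(
                f"- {r['facility_id']}: {r['flag']} ({direction}), "
                f"p = {r['p_value']:.2e}, z = {r['z']:.2f} "
                f"[{r['method']} over-dispersion]")
    if not any_flag:
        lines.append("\nNo outliers detected on any indicator.")

    lines.append("\n## Composite performance")
    inc = composite[composite["included"]]
    out = inc[inc["performance_class"] != "typical"]
    thr = cfg.composite.threshold
    if out.empty:
        lines.append(f"no facilities beyond +/-{thr}")
    else:
        for _, r in out.sort_values("composite", ascending=False).iterrows():
            lines.append(f"- {r['facility_id']}: Z = {r['composite']:.2f} "
                         f"-> {r['performance_class']}")
    excl = composite[~composite["included"]]
    for _, r in excl.iterrows():
        lines.append(f"- {r['facility_id']}: excluded - insufficient "
                     f"indicators ({int(r['n_available'])} of 6 available)")
    lines.append("")
    return "\n".join(lines)
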