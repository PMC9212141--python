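"""End-to-end pipeline stages driven by a :class:`~sdgcurves.config.PipelineConfig`.

Each stage reads only files (plus the built-in registry), writes
deterministic CSV artifacts into the output directory, and records its row
counts in ``manifest.json`` together with the config hash and seed, so two
runs with identical config and inputs are byte-identical and every stage is
re-runnable from the previous stage's files alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from . import estimation, forecast, gap, synthetic
from .config import PipelineConfig
from .io import (
    read_covariates,
    read_growth_scenarios,
    read_observations,
    write_growth_scenarios,
    write_table,
)
from .registry import load_registry

__all__ = [
    "stage_simulate", "stage_fit", "stage_gap", "stage_forecast",
    "stage_aggregate", "run_all", "STAGES",
]

logger = logging.getLogger("sdgcurves")


def _update_manifest(cfg: PipelineConfig, stage: str, counts: dict) -> None:
    path = cfg.out / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text("utf-8"))
    manifest["config_sha256"] = cfg.config_hash
    manifest["seed"] = cfg.seed
    manifest.setdefault("stages", {})[stage] = counts
    cfg.out.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8")


def _registry(cfg: PipelineConfig):
    return load_registry(cfg.path("registry"))


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate synthetic observations, covariates and growth scenarios."""
    block = dict(cfg.synthetic)
    block.setdefault("seed", cfg.seed)
    if "years" in block:
        block["years"] = tuple(block["years"])
    spec = synthetic.SyntheticSpec(**block)
    obs, cov, _ = synthetic.generate_panel(spec)
    countries = sorted(cov["country"].unique())
    latest = cov.sort_values("year").groupby("country").tail(1)
    base_gdp = dict(zip(latest["country"], latest["gdp_pc"]))
    scen = synthetic.generate_growth_scenarios(
        countries,
        baseline_year=spec.years[1],
        end_year=2030,
        seed=spec.seed + 1,
        baseline_gdp_pc=base_gdp,
    )
    write_table(obs, cfg.out / "observations.csv", "observations")
    write_table(cov, cfg.out / "covariates.csv", "covariates")
    write_growth_scenarios(scen, cfg.out / "scenarios.csv")
    counts = {"observations": len(obs), "covariates": len(cov),
              "scenarios": len(scen)}
    _update_manifest(cfg, "simulate", counts)
    return counts


def _input(cfg: PipelineConfig, key: str, default_name: str) -> Path:
    p = cfg.path(key)
    return p if p is not None else cfg.out / default_name


def stage_fit(cfg: PipelineConfig) -> dict:
    """Fit an evolution curve for every registry indicator in the data."""
    obs = read_observations(_input(cfg, "observations", "observations.csv"))
    cov = read_covariates(_input(cfg, "covariates", "covariates.csv"))
    registry = _registry(cfg)
    fits = estimation.fit_all(
        obs, cov, registry, width=cfg.period_width, anchor=cfg.anchor_year
    )
    frame = estimation.fits_to_frame(fits)
    write_table(frame, cfg.out / "fits.csv", "fits")
    counts = {"fits": len(fits), "rows": len(frame)}
    _update_manifest(cfg, "fit", counts)
    return counts


def _load_fits(cfg: PipelineConfig) -> dict:
    df = pd.read_csv(cfg.out / "fits.csv", dtype={"code": str, "term": str})
    return estimation.fits_from_frame(df)


def stage_gap(cfg: PipelineConfig) -> dict:
    """Compute the gap scorecard from fitted curves."""
    obs = read_observations(_input(cfg, "observations", "observations.csv"))
    cov = read_covariates(_input(cfg, "covariates", "covariates.csv"))
    registry = _registry(cfg)
    fits = _load_fits(cfg)
    scorecard = gap.run_gaps(
        obs, cov, fits, registry,
        window=cfg.baseline_window,
        anchor_mode=cfg.anchor_mode,
        alpha=cfg.alpha,
        better=cfg.class_better,
        worse=cfg.class_worse,
    )
    write_table(scorecard, cfg.out / "gaps.csv", "gaps")
    counts = {"gaps": len(scorecard)}
    _update_manifest(cfg, "gap", counts)
    return counts


def stage_forecast(cfg: PipelineConfig) -> dict:
    """Project gated indicators to the scenario horizon."""
    obs = read_observations(_input(cfg, "observations", "observations.csv"))
    scen = read_growth_scenarios(_input(cfg, "scenarios", "scenarios.csv"))
    registry = _registry(cfg)
    fits = _load_fits(cfg)
    lo, hi = cfg.baseline_window
    win = obs.loc[obs["year"] >= lo]
    if hi is not None:
        win = win.loc[win["year"] <= hi]
    baselines = (
        win.loc[win["code"].isin(fits)]
        .groupby(["country", "code"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "baseline_value"})
    )
    table = forecast.run_forecasts(fits, scen, baselines, registry, alpha=cfg.alpha)
    write_table(table, cfg.out / "forecasts.csv", "forecasts")
    counts = {"forecasts": len(table),
              "included": int(table["included"].sum()) if len(table) else 0}
    _update_manifest(cfg, "forecast", counts)
    return counts


def stage_aggregate(cfg: PipelineConfig) -> dict:
    """Aggregate forecast gains into theme progress and subregional means."""
    table = pd.read_csv(cfg.out / "forecasts.csv", dtype={"code": str})
    registry = _registry(cfg)
    progress = agg.theme_progress(table, registry)
    write_table(progress, cfg.out / "theme_progress.csv", "theme_progress")
    if cfg.subregion_source == "printed":
        membership, exclusions = agg.default_membership()
    else:
        cov = read_covariates(_input(cfg, "covariates", "covariates.csv"))
        membership = dict(
            cov.drop_duplicates("country")[["country", "region"]].itertuples(
                index=False, name=None
            )
        )
        exclusions = ()
    summary = agg.subregion_mean(progress, membership, exclusions)
    write_table(summary, cfg.out / "subregions.csv", "subregions")
    counts = {"theme_progress": len(progress), "subregions": len(summary)}
    _update_manifest(cfg, "aggregate", counts)
    return counts


STAGES = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "gap": stage_gap,
    "forecast": stage_forecast,
    "aggregate": stage_aggregate,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order, returning the merged stage counts."""
    results = {}
    for name, fn in STAGES.items():
        logger.info("running stage %s", name)
        results[name] = fn(cfg)
    return results
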