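"""Counterfactual levels and the direction-adjusted gap index.

For each country x indicator, the observed post-2015 average is compared
with the counterfactual level predicted by the indicator's global evolution
curve at the country's own covariates — excluding the country's fixed
effect, so the curve acts as an average global benchmark rather than a
self-prediction. The gap

    gap = direction * (observed - expected) / expected

is adjusted so that improvement always points upward: a gap of -0.3 means
the country is 30% worse than expected, +0.5 means 50% better, regardless
of whether the indicator improves by falling (mortality) or rising
(coverage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimation import CurveFit, significance_gate
from .registry import ThemeRegistry

__all__ = [
    "MissingDataError",
    "observed_baseline",
    "counterfactual",
    "gap_index",
    "classify_gap",
    "run_gaps",
]

logger = logging.getLogger("sdgcurves")

#: default post-2015 averaging window (inclusive start, open end)
DEFAULT_WINDOW: tuple[int, int | None] = (2015, None)


class MissingDataError(ValueError):
    """No observations or covariates available where some were required."""


def observed_baseline(
    obs: pd.DataFrame,
    country: str,
    code: str,
    window: tuple[int, int | None] = DEFAULT_WINDOW,
) -> tuple[float, int]:
    """Arithmetic mean (and count) of observations in the window (default >= 2015)."""
    lo, hi = window
    m = (obs["country"] == country) & (obs["code"] == code) & (obs["year"] >= lo)
    if hi is not None:
        m &= obs["year"] <= hi
    values = obs.loc[m, "value"]
    if values.empty:
        raise MissingDataError(
            f"no observations for ({country}, {code}) in window {window}"
        )
    return float(values.mean()), int(len(values))


def counterfactual(
    fit: CurveFit,
    gdp_pc: float,
    health_exp: float,
    gini: float,
    region: str,
    period_effect: str = "latest",
) -> float:
    """Curve-predicted indicator level at the given covariates.

    Country fixed effects are excluded by construction. For panel fits the
    period effect of the most recent estimated period enters by default
    (``period_effect="mean"`` uses the average effect instead). A regional
    dummy coefficient enters only if it was retained in the fit.
    """
    if "ln_gdp_pc" not in fit.params:
        raise MissingDataError(f"fit for {fit.code} has no GDPpc coefficient")
    covs = {"gdp_pc": gdp_pc, "health_exp": health_exp, "gini": gini}
    for name, v in covs.items():
        needed = name != "gdp_pc" and name in fit.params or name == "gdp_pc"
        if needed and (v is None or not np.isfinite(v)):
            raise MissingDataError(f"missing covariate {name} for {fit.code}")
    if gdp_pc <= 0:
        raise MissingDataError(f"non-positive gdp_pc for {fit.code}")
    lp = fit.params.get("const", 0.0)
    lp += fit.params["ln_gdp_pc"] * np.log(gdp_pc)
    lp += fit.params.get("health_exp", 0.0) * health_exp
    lp += fit.params.get("gini", 0.0) * gini
    lp += fit.params.get(f"region_{region}", 0.0)
    if fit.period_effects:
        lp += fit.mean_period_effect if period_effect == "mean" else fit.latest_period_effect
    return float(np.exp(lp))


def gap_index(observed: float, expected: float, direction: int) -> float:
    """Direction-adjusted relative difference between observed and expected.

    ``direction`` is +1 for higher-is-better indicators and -1 for
    lower-is-better ones; positive gaps always mean better than expected.
    """
    if expected <= 0:
        raise ValueError(f"expected level must be > 0, got {expected}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    return direction * (observed - expected) / expected


def classify_gap(gap: float, better: float = 0.1, worse: float = -0.1) -> str:
    """Scorecard band: 'better' (>= +0.1), 'as expected', or 'worse' (<= -0.1)."""
    if gap >= better:
        return "better"
    if gap <= worse:
        return "worse"
    return "as expected"


def run_gaps(
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    fits: dict[str, CurveFit],
    registry: ThemeRegistry,
    window: tuple[int, int | None] = DEFAULT_WINDOW,
    anchor_mode: str = "window_average",
    alpha: float = 0.05,
    better: float = 0.1,
    worse: float = -0.1,
) -> pd.DataFrame:
    """Compute the gap scorecard for every (country, gated indicator) pair.

    Covariates enter at their window averages (``anchor_mode="latest"``
    uses each country's most recent year in the window instead).
    Indicators whose curve fails the significance gate, and country x
    indicator pairs without a baseline or covariates, are skipped and
    logged.
    """
    lo, hi = window
    cwin = cov.loc[cov["year"] >= lo]
    if hi is not None:
        cwin = cwin.loc[cwin["year"] <= hi]
    if anchor_mode == "latest":
        cwin = cwin.sort_values("year").groupby("country", as_index=False).tail(1)
    elif anchor_mode != "window_average":
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    cavg = cwin.groupby("country", as_index=False).agg(
        gdp_pc=("gdp_pc", "mean"),
        gini=("gini", "mean"),
        health_exp=("health_exp", "mean"),
        region=("region", "first"),
    ).set_index("country")

    rows = []
    for code, fit in sorted(fits.items()):
        if code not in registry:
            continue
        if not significance_gate(fit, alpha):
            logger.info("gap: %s omitted (GDPpc parameter not significant)", code)
            continue
        meta = registry.meta(code)
        for country in sorted(obs.loc[obs["code"] == code, "country"].unique()):
            try:
                observed, n_post = observed_baseline(obs, country, code, window)
            except MissingDataError as err:
                logger.info("gap: skipped %s x %s: %s", country, code, err)
                continue
            if country not in cavg.index:
                logger.info("gap: skipped %s x %s: no covariates in window",
                            country, code)
                continue
            c = cavg.loc[country]
            try:
                expected = counterfactual(
                    fit, c["gdp_pc"], c["health_exp"], c["gini"], c["region"]
                )
            except MissingDataError as err:
                logger.info("gap: skipped %s x %s: %s", country, code, err)
                continue
            g = gap_index(observed, expected, meta.direction)
            rows.append({
                "country": country, "code": code, "theme": meta.theme,
                "direction": meta.direction, "observed": observed,
                "expected": expected, "gap": g,
                "class": classify_gap(g, better, worse),
                "n_post2015": n_post,
            })
    return pd.DataFrame(
        rows,
        columns=["country", "code", "theme", "direction", "observed",
                 "expected", "gap", "class", "n_post2015"],
    )
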