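"""2030 projections from estimated GDPpc elasticities and growth scenarios.

Under the log-log curve, holding Gini and health expenditure constant over
the decade, every non-GDP term cancels between the baseline and horizon
years, so an indicator projects as

    projected = baseline * (1 + G)**b1

where ``G`` is the cumulative GDP-per-capita growth over the horizon
(``prod(1 + g_t) - 1`` over annual rates, equivalently the endpoint GDPpc
ratio minus one) and ``b1`` the estimated elasticity. Projections are made
only for indicators whose curve passes the GDPpc significance gate; gains
are direction-adjusted so that improvement is always positive.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .estimation import CurveFit, significance_gate
from .registry import ThemeRegistry

__all__ = [
    "cumulative_growth",
    "growth_from_endpoints",
    "project_indicator",
    "adjusted_gain",
    "scenario_cumulative",
    "run_forecasts",
    "load_printed_gdp",
]

logger = logging.getLogger("sdgcurves")


def cumulative_growth(annual_rates: Iterable[float]) -> float:
    """Compound annual growth fractions: prod(1 + g_t) - 1."""
    rates = np.asarray(list(annual_rates), dtype=float)
    if (rates <= -1).any():
        raise ValueError("annual growth rates must exceed -1")
    return float(np.prod(1.0 + rates) - 1.0)


def growth_from_endpoints(gdp_start: float, gdp_end: float) -> float:
    """Cumulative growth implied by baseline and horizon GDPpc levels."""
    if gdp_start <= 0 or gdp_end <= 0:
        raise ValueError("GDP per capita endpoints must be > 0")
    return gdp_end / gdp_start - 1.0


def project_indicator(baseline_value: float, beta_gdp: float,
                      cum_growth: float) -> float:
    """Project an indicator level through cumulative GDPpc growth."""
    if baseline_value <= 0:
        raise ValueError("baseline value must be > 0")
    if cum_growth <= -1:
        raise ValueError("cumulative growth must exceed -1")
    return baseline_value * (1.0 + cum_growth) ** beta_gdp


def adjusted_gain(baseline: float, projected: float, direction: int) -> float:
    """Direction-adjusted relative change; positive always means improvement."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    return direction * (projected - baseline) / baseline


def scenario_cumulative(scenarios: pd.DataFrame) -> pd.Series:
    """Cumulative growth per country from a scenario table's g<year> columns."""
    gcols = sorted(
        (c for c in scenarios.columns if c.startswith("g") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    out = {
        row["country"]: cumulative_growth(row[gcols].to_numpy(float))
        for _, row in scenarios.iterrows()
    }
    return pd.Series(out, name="cumulative")


def run_forecasts(
    fits: dict[str, CurveFit],
    scenarios: pd.DataFrame,
    baselines: pd.DataFrame,
    registry: ThemeRegistry,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Project every (country, indicator) baseline to the scenario horizon.

    ``baselines`` has columns ``country, code, baseline_value`` (typically
    post-2015 averages, matching the gap stage's anchoring). Indicators
    failing the significance gate are emitted with ``included=False`` and
    no projection; countries without a scenario are skipped and logged.
    """
    cum = scenario_cumulative(scenarios)
    gate: dict[str, bool] = {
        code: significance_gate(fit, alpha) for code, fit in fits.items()
    }
    rows = []
    for _, row in baselines.sort_values(["country", "code"]).iterrows():
        country, code = row["country"], row["code"]
        if code not in fits or code not in registry:
            continue
        if country not in cum.index:
            logger.info("forecast: skipped %s (no growth scenario)", country)
            continue
        meta = registry.meta(code)
        base = float(row["baseline_value"])
        if gate[code]:
            proj = project_indicator(base, fits[code].beta_gdp, cum[country])
            raw = proj / base - 1.0
            adj = adjusted_gain(base, proj, meta.direction)
        else:
            proj = raw = adj = np.nan
        rows.append({
            "country": country, "code": code, "theme": meta.theme,
            "baseline_value": base, "projected_2030": proj,
            "raw_gain": raw, "adjusted_gain": adj, "included": gate[code],
        })
    return pd.DataFrame(
        rows,
        columns=["country", "code", "theme", "baseline_value",
                 "projected_2030", "raw_gain", "adjusted_gain", "included"],
    )


def load_printed_gdp() -> pd.DataFrame:
    """Bundled 2019 baseline and projected 2030 GDP per capita for the 33
    American countries, with subregion membership and the two printed
    subregion-mean exclusions (Mexico, Guyana)."""
    text = (
        resources.files("sdgcurves.data")
        .joinpath("gdp_scenarios_2030.csv")
        .read_text("utf-8")
    )
    rows = list(csv.DictReader(text.splitlines()))
    df = pd.DataFrame(rows)
    df["gdp_pc_2019"] = df["gdp_pc_2019"].astype(float)
    df["gdp_pc_2030"] = df["gdp_pc_2030"].astype(float)
    df["excluded_from_subregion_mean"] = (
        df["excluded_from_subregion_mean"].str.lower() == "true"
    )
    return df
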