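"""Theme-level progress and subregional summaries.

A country's progress in a health theme is the sum of its direction-adjusted
projected gains over the theme's indicators, divided by the theme's FULL
registry size — so a missing indicator shrinks measured progress
proportionally rather than being averaged away. Subregional summaries are
unweighted means of member-country progress, with configurable exclusions
(by default Mexico is excluded from the North America mean and Guyana from
the South America mean, matching the published summary rows).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .forecast import load_printed_gdp
from .registry import THEMES, ThemeRegistry

__all__ = ["theme_progress", "subregion_mean", "default_membership"]

logger = logging.getLogger("sdgcurves")


def theme_progress(forecasts: pd.DataFrame, registry: ThemeRegistry) -> pd.DataFrame:
    """Per-country, per-theme progress from a forecast table.

    Only rows with ``included=True`` and a finite ``adjusted_gain``
    contribute; the divisor is always the theme's full indicator count.
    Themes with no contributing indicator report progress 0.
    """
    sizes = registry.theme_sizes
    rows = []
    inc = forecasts.loc[
        forecasts["included"].astype(bool) & forecasts["adjusted_gain"].notna()
    ]
    for country in sorted(forecasts["country"].unique()):
        sub = inc.loc[inc["country"] == country]
        for theme in THEMES:
            if theme not in sizes:
                continue
            gains = sub.loc[sub["theme"] == theme, "adjusted_gain"]
            rows.append({
                "country": country,
                "theme": theme,
                "progress": float(gains.sum()) / sizes[theme] if len(gains) else 0.0,
                "n_available": int(len(gains)),
                "n_theme": sizes[theme],
            })
    return pd.DataFrame(
        rows, columns=["country", "theme", "progress", "n_available", "n_theme"]
    )


def default_membership() -> tuple[Mapping[str, str], tuple[str, ...]]:
    """Bundled subregion membership for the 33 American countries and the
    printed exclusions (Mexico, Guyana)."""
    gdp = load_printed_gdp()
    membership = dict(zip(gdp["country"], gdp["subregion"]))
    exclusions = tuple(gdp.loc[gdp["excluded_from_subregion_mean"], "country"])
    return membership, exclusions


def subregion_mean(
    progress: pd.DataFrame,
    membership: Mapping[str, str] | None = None,
    exclusions: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Unweighted subregional mean of per-country theme progress.

    Countries not in the membership mapping are ignored; excluded
    countries are removed before averaging; a subregion left empty after
    exclusions is omitted (logged).
    """
    if membership is None or exclusions is None:
        default_map, default_excl = default_membership()
        membership = membership if membership is not None else default_map
        exclusions = exclusions if exclusions is not None else default_excl
    excl = set(exclusions)
    df = progress.loc[
        progress["country"].isin(membership) & ~progress["country"].isin(excl)
    ].copy()
    df["subregion"] = df["country"].map(dict(membership))

    rows = []
    for subregion in sorted(set(membership.values())):
        sub = df.loc[df["subregion"] == subregion]
        if sub.empty:
            logger.info("subregion %s empty after exclusions; omitted", subregion)
            continue
        for theme, tsub in sub.groupby("theme"):
            rows.append({
                "subregion": subregion,
                "theme": theme,
                "mean_progress": float(tsub["progress"].mean()),
                "n_countries": int(tsub["country"].nunique()),
            })
    return pd.DataFrame(
        rows, columns=["subregion", "theme", "mean_progress", "n_countries"]
    )
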