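"""CSV readers and writers for every tabular artifact of the pipeline.

All inputs and outputs are long (tidy) UTF-8 CSV files with a mandatory
header. Readers validate strictly and reject malformed rows with their row
numbers rather than silently coercing them; writers are deterministic —
fixed column order, rows sorted on the schema's key, floats rendered with 6
significant digits — so identical inputs yield byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WHO_REGIONS",
    "SchemaError",
    "IntegrityError",
    "read_observations",
    "read_covariates",
    "read_growth_scenarios",
    "write_table",
    "write_growth_scenarios",
    "OUTPUT_SCHEMAS",
]

#: The six WHO regional groupings used as dummies.
WHO_REGIONS: tuple[str, ...] = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")

#: Default admissible calendar-year range for observations.
YEAR_RANGE: tuple[int, int] = (1982, 2030)


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


class IntegrityError(ValueError):
    """A file violates a uniqueness or domain constraint."""


# (columns, sort keys) per output schema tag
OUTPUT_SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "observations": (["country", "year", "code", "value"], ["country", "year", "code"]),
    "covariates": (
        ["country", "year", "gdp_pc", "gini", "health_exp", "region"],
        ["country", "year"],
    ),
    "fits": (
        ["code", "method", "term", "estimate", "std_error", "p_value", "dropped",
         "n_obs", "r2", "rmse", "f_stat", "corr_fe"],
        ["code", "term"],
    ),
    "gaps": (
        ["country", "code", "theme", "direction", "observed", "expected", "gap",
         "class", "n_post2015"],
        ["country", "code"],
    ),
    "forecasts": (
        ["country", "code", "theme", "baseline_value", "projected_2030",
         "raw_gain", "adjusted_gain", "included"],
        ["country", "code"],
    ),
    "theme_progress": (
        ["country", "theme", "progress", "n_available", "n_theme"],
        ["country", "theme"],
    ),
    "subregions": (
        ["subregion", "theme", "mean_progress", "n_countries"],
        ["subregion", "theme"],
    ),
}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path, allow_missing: bool = False) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = out.isna() & ~blank
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 0-base
        raise SchemaError(f"{path}: non-numeric {col!r} in row(s) {rows}")
    if not allow_missing and (out.isna()).any():
        rows = [int(i) + 2 for i in df.index[out.isna()][:5]]
        raise SchemaError(f"{path}: missing {col!r} in row(s) {rows}")
    return out


def read_observations(path, year_range: tuple[int, int] = YEAR_RANGE) -> pd.DataFrame:
    """Read a long observation panel (country, year, code, value)."""
    df = pd.read_csv(path, dtype={"country": str, "code": str})
    _require_columns(df, ["country", "year", "code", "value"], path)
    df = df[["country", "year", "code", "value"]].copy()
    df["year"] = _numeric(df, "year", path).astype(int)
    df["value"] = _numeric(df, "value", path)
    if not np.isfinite(df["value"]).all():
        rows = [int(i) + 2 for i in df.index[~np.isfinite(df["value"])][:5]]
        raise IntegrityError(f"{path}: non-finite value in row(s) {rows}")
    lo, hi = year_range
    off = (df["year"] < lo) | (df["year"] > hi)
    if off.any():
        rows = [int(i) + 2 for i in df.index[off][:5]]
        raise IntegrityError(f"{path}: year outside [{lo}, {hi}] in row(s) {rows}")
    dup = df.duplicated(["country", "year", "code"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (country, year, code) = "
            f"({first['country']}, {first['year']}, {first['code']})"
        )
    return df


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate panel (country, year, gdp_pc, gini, health_exp, region)."""
    df = pd.read_csv(path, dtype={"country": str, "region": str})
    _require_columns(df, ["country", "year", "gdp_pc", "gini", "health_exp", "region"], path)
    df = df[["country", "year", "gdp_pc", "gini", "health_exp", "region"]].copy()
    df["year"] = _numeric(df, "year", path).astype(int)
    for col in ("gdp_pc", "gini", "health_exp"):
        df[col] = _numeric(df, col, path, allow_missing=True)
    df["region"] = df["region"].str.strip().str.upper()
    unknown = ~df["region"].isin(WHO_REGIONS)
    if unknown.any():
        first = df[unknown].iloc[0]
        raise SchemaError(
            f"{path}: unknown region label {first['region']!r} "
            f"(row {int(df.index[unknown][0]) + 2}); expected one of {list(WHO_REGIONS)}"
        )
    nonpos = df["gdp_pc"].notna() & (df["gdp_pc"] <= 0)
    if nonpos.any():
        rows = [int(i) + 2 for i in df.index[nonpos][:5]]
        raise IntegrityError(f"{path}: gdp_pc must be > 0; violated in row(s) {rows}")
    dup = df.duplicated(["country", "year"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (country, year) = ({first['country']}, {first['year']})"
        )
    varying = df.groupby("country")["region"].nunique()
    if (varying > 1).any():
        bad = varying[varying > 1].index[0]
        raise IntegrityError(f"{path}: region not constant within country {bad!r}")
    return df


def read_growth_scenarios(path) -> pd.DataFrame:
    """Read a growth-scenario table.

    Columns: ``country, baseline_year, baseline_gdp_pc`` then one ``g<year>``
    column per horizon year holding that year's GDP-per-capita growth
    fraction (e.g. 0.03 for 3%).
    """
    df = pd.read_csv(path, dtype={"country": str})
    _require_columns(df, ["country", "baseline_year", "baseline_gdp_pc"], path)
    gcols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    if not gcols:
        raise SchemaError(f"{path}: no growth-rate columns (g<year>) found")
    gcols = sorted(gcols, key=lambda c: int(c[1:]))
    df = df[["country", "baseline_year", "baseline_gdp_pc"] + gcols].copy()
    df["baseline_year"] = _numeric(df, "baseline_year", path).astype(int)
    df["baseline_gdp_pc"] = _numeric(df, "baseline_gdp_pc", path)
    for c in gcols:
        df[c] = _numeric(df, c, path)
        if (df[c] <= -1).any():
            rows = [int(i) + 2 for i in df.index[df[c] <= -1][:5]]
            raise IntegrityError(f"{path}: growth rate <= -1 in {c!r}, row(s) {rows}")
    if df["country"].duplicated().any():
        dup = df.loc[df["country"].duplicated(), "country"].iloc[0]
        raise IntegrityError(f"{path}: duplicate scenario for country {dup!r}")
    return df


def write_table(records: pd.DataFrame, path, schema: str) -> None:
    """Write *records* under a declared output schema, deterministically.

    Rows are sorted on the schema key, columns emitted in the declared
    order, floats rendered with 6 significant digits, missing values as
    empty fields.
    """
    if schema not in OUTPUT_SCHEMAS:
        raise SchemaError(f"unknown output schema {schema!r}")
    columns, keys = OUTPUT_SCHEMAS[schema]
    df = pd.DataFrame(records, columns=None).copy()
    missing = [c for c in columns if c not in df.columns]
    if missing and len(df):
        raise SchemaError(f"records for schema {schema!r} missing column(s) {missing}")
    if not len(df):
        df = pd.DataFrame(columns=columns)
    df = df[columns].sort_values(keys, kind="mergesort").reset_index(drop=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_growth_scenarios(records: pd.DataFrame, path) -> None:
    """Write a scenario table (variable per-year growth columns)."""
    df = pd.DataFrame(records).copy()
    fixed = ["country", "baseline_year", "baseline_gdp_pc"]
    gcols = sorted(
        (c for c in df.columns if c.startswith("g") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    df = df[fixed + gcols].sort_values("country", kind="mergesort").reset_index(drop=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
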