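"""Per-indicator global evolution curves.

Each indicator's curve is a log-log regression of the indicator level on
GDP per capita with Gini and public-health-expenditure controls and WHO
regional dummies (AFR reference):

    ln(value) = const + b1*ln(gdp_pc) + b2*health_exp + b3*gini + b4*D + fe + e

Indicators with a long multi-period history are fitted as two-way
fixed-effects panels on 5-year period averages: the within transformation
demeans by country, period indicator terms absorb common shocks, region
dummies (time-invariant within country) are detected as collinear with the
country effects and dropped, and coefficient covariances are clustered by
country. SDG-era indicators observed in essentially one period get a
heteroskedasticity-robust (HC1) cross-sectional OLS in which the regional
dummies are retained.

A transcription of the published coefficient table is bundled
(:func:`load_printed_curves`); its significance markers are encoded as
p-value bounds so the same gate logic applies to printed and fitted curves.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import WHO_REGIONS
from .registry import ThemeRegistry

__all__ = [
    "PanelDesign",
    "CurveFit",
    "DegenerateDesignError",
    "GateError",
    "period_average",
    "build_design",
    "fit_panel_fe",
    "fit_cross_section",
    "fit_indicator",
    "fit_all",
    "choose_method",
    "significance_gate",
    "load_printed_curves",
    "fits_to_frame",
    "fits_from_frame",
]

logger = logging.getLogger("sdgcurves")

#: structural regressor names, in declared order (collinearity ties are
#: broken by dropping the later column in this order)
STRUCTURAL_TERMS = ["ln_gdp_pc", "health_exp", "gini"] + [
    f"region_{r}" for r in WHO_REGIONS[1:]
]

#: encoded p-value bounds for printed significance markers (stars count)
_STARS_P = {3: 1e-4, 2: 5e-3, 1: 2.5e-2, 0: 0.5}


class DegenerateDesignError(ValueError):
    """The design has too few rows or too little rank to estimate."""


class GateError(ValueError):
    """The significance gate was applied to a fit without a GDPpc term."""


@dataclass
class PanelDesign:
    """Assembled regression design for one indicator."""

    code: str
    y: np.ndarray  # ln(value)
    X: np.ndarray  # columns in `columns` order
    columns: list[str]
    country: np.ndarray
    period: np.ndarray
    method_tag: str  # "panel_fe" | "cross_section"
    n_dropped: int = 0  # rows lost to listwise deletion / log-domain rule

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class CurveFit:
    """Estimated evolution-curve parameters and fit statistics."""

    code: str
    method: str  # "panel_fe" | "cross_section" | "printed"
    params: dict[str, float]
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()
    n_obs: int = 0
    r2: float = float("nan")
    rmse: float = float("nan")
    f_stat: float = float("nan")
    corr_fe: float | None = None
    period_effects: dict[int, float] | None = None  # anchor year -> effect

    @property
    def beta_gdp(self) -> float:
        return self.params["ln_gdp_pc"]

    @property
    def p_beta_gdp(self) -> float:
        return self.p_values["ln_gdp_pc"]

    @property
    def latest_period_effect(self) -> float:
        if not self.period_effects:
            return 0.0
        return self.period_effects[max(self.period_effects)]

    @property
    def mean_period_effect(self) -> float:
        if not self.period_effects:
            return 0.0
        return float(np.mean(list(self.period_effects.values())))


# ---------------------------------------------------------------------------
# period averaging
# ---------------------------------------------------------------------------

def period_average(
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    width: int = 5,
    anchor: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average observations and covariates within calendar-year bins.

    Bins are anchored at *anchor* (default 2000) with the given *width*:
    [2000-2004], [2005-2009], ... and pre-anchor bins analogously. A bin
    exists whenever it contains at least one observation. The returned
    tables carry a ``period`` column holding the bin's first year; with
    ``width=1`` the operation is the identity relabelling ``year`` as
    ``period``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")

    def bin_of(years: pd.Series) -> pd.Series:
        return anchor + ((years - anchor) // width) * width

    o = obs.copy()
    o["period"] = bin_of(o["year"])
    obs_p = (
        o.groupby(["country", "period", "code"], as_index=False)["value"]
        .mean()
        .loc[:, ["country", "period", "code", "value"]]
    )

    c = cov.copy()
    c["period"] = bin_of(c["year"])
    cov_p = c.groupby(["country", "period"], as_index=False).agg(
        gdp_pc=("gdp_pc", "mean"),
        gini=("gini", "mean"),
        health_exp=("health_exp", "mean"),
        region=("region", "first"),
    )
    return obs_p, cov_p


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def build_design(
    obs_p: pd.DataFrame,
    cov_p: pd.DataFrame,
    registry: ThemeRegistry,
    code: str,
    method_tag: str,
) -> PanelDesign:
    """Assemble the regression design for one indicator.

    The response is ``ln(value)``; GDP per capita enters in logs, Gini and
    health expenditure untransformed; region dummies use AFR as reference.
    Rows with any missing field or a non-positive value/GDPpc are removed
    listwise (logged). For cross-sections the latest populated period per
    country is used, giving one record per country.
    """
    registry.meta(code)  # raises on unknown code
    sub = obs_p.loc[obs_p["code"] == code]
    merged = sub.merge(cov_p, on=["country", "period"], how="left")

    if method_tag == "cross_section":
        merged = (
            merged.sort_values(["country", "period"])
            .groupby("country", as_index=False)
            .tail(1)
        )

    n0 = len(merged)
    ok = (
        merged["value"].notna() & (merged["value"] > 0)
        & merged["gdp_pc"].notna() & (merged["gdp_pc"] > 0)
        & merged["health_exp"].notna()
        & merged["gini"].notna()
        & merged["region"].notna()
    )
    kept = merged.loc[ok].sort_values(["country", "period"]).reset_index(drop=True)
    n_dropped = n0 - len(kept)
    if n_dropped:
        logger.info("design %s: dropped %d row(s) (missing fields or log-domain rule)",
                    code, n_dropped)

    y = np.log(kept["value"].to_numpy(float))
    cols = {
        "ln_gdp_pc": np.log(kept["gdp_pc"].to_numpy(float)),
        "health_exp": kept["health_exp"].to_numpy(float),
        "gini": kept["gini"].to_numpy(float),
    }
    for r in WHO_REGIONS[1:]:  # AFR is the reference
        cols[f"region_{r}"] = (kept["region"] == r).to_numpy(float)
    X = np.column_stack([cols[t] for t in STRUCTURAL_TERMS])

    if len(kept) < X.shape[1] + 1:
        raise DegenerateDesignError(
            f"indicator {code}: {len(kept)} usable row(s) for "
            f"{X.shape[1]} regressor(s)"
        )
    return PanelDesign(
        code=code,
        y=y,
        X=X,
        columns=list(STRUCTURAL_TERMS),
        country=kept["country"].to_numpy(),
        period=kept["period"].to_numpy(int),
        method_tag=method_tag,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# numerics shared by both estimators
# ---------------------------------------------------------------------------

def _greedy_rank_keep(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Keep a maximal independent prefix-greedy column subset.

    Columns are scanned in declared order; a column linearly dependent on
    the columns already kept is dropped, so ties are always resolved by
    dropping the later column.
    """
    keep: list[int] = []
    dropped: list[str] = []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        r = v.copy()
        for q in Q:
            r -= (q @ v) * q
        if np.linalg.norm(r) > tol * max(1.0, np.linalg.norm(v)):
            Q.append(r / np.linalg.norm(r))
            keep.append(j)
        else:
            dropped.append(names[j])
    return keep, dropped


def _demean_by(arr: np.ndarray, groups: np.ndarray) -> np.ndarray:
    df = pd.DataFrame(arr)
    return arr - df.groupby(pd.Series(groups)).transform("mean").to_numpy()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def fit_panel_fe(design: PanelDesign) -> CurveFit:
    """Two-way fixed-effects fit via the within (country-demeaning) transform.

    Period indicator terms (first period as reference) absorb common
    shocks; any column that is constant within countries — the region
    dummies in particular — vanishes under demeaning and is recorded in
    the dropped set. The coefficient covariance is clustered by country
    (CR1 small-sample correction) and p-values use a t distribution with
    (clusters - 1) degrees of freedom.
    """
    if design.method_tag != "panel_fe":
        raise ValueError("design was not assembled for panel_fe")
    countries, periods = design.country, design.period
    uniq_c = np.unique(countries)
    uniq_p = np.sort(np.unique(periods))
    if len(uniq_p) < 2 or len(uniq_c) < 2:
        raise DegenerateDesignError(
            f"indicator {design.code}: panel needs >= 2 periods for >= 2 countries"
        )

    pnames = [f"period_{p}" for p in uniq_p[1:]]
    P = np.column_stack([(periods == p).astype(float) for p in uniq_p[1:]])
    X_full = np.hstack([design.X, P])
    names = design.columns + pnames

    yd = _demean_by(design.y[:, None], countries)[:, 0]
    Xd = _demean_by(X_full, countries)

    # columns annihilated by the within transform (time-invariant regressors)
    col_norm = np.linalg.norm(Xd, axis=0)
    orig_norm = np.linalg.norm(X_full, axis=0)
    alive = col_norm > 1e-10 * np.maximum(1.0, orig_norm)
    dropped = [n for n, a in zip(names, alive) if not a]
    if dropped:
        logger.info("fit %s: dropped collinear column(s) under country FE: %s",
                    design.code, dropped)
    idx_alive = np.flatnonzero(alive)
    keep_rel, rank_dropped = _greedy_rank_keep(
        Xd[:, idx_alive], [names[i] for i in idx_alive]
    )
    dropped += rank_dropped
    keep = idx_alive[keep_rel]
    kept_names = [names[i] for i in keep]
    Xk, Xk_orig = Xd[:, keep], X_full[:, keep]

    n, k = Xk.shape
    G = len(uniq_c)
    df_resid = n - G - k
    if df_resid < 1:
        raise DegenerateDesignError(
            f"indicator {design.code}: no residual degrees of freedom "
            f"(n={n}, countries={G}, k={k})"
        )

    beta, *_ = np.linalg.lstsq(Xk, yd, rcond=None)
    u = yd - Xk @ beta
    ssr = float(u @ u)
    sst = float(yd @ yd)
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    rmse = float(np.sqrt(ssr / df_resid))

    bread = np.linalg.inv(Xk.T @ Xk)
    meat = np.zeros((k, k))
    for g in uniq_c:
        m = countries == g
        s = Xk[m].T @ u[m]
        meat += np.outer(s, s)
    c_cr1 = (G / (G - 1)) * ((n - 1) / df_resid)
    V = c_cr1 * bread @ meat @ bread
    se = np.sqrt(np.diag(V))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=G - 1)

    # constant chosen so that the estimated country effects average to zero
    const = float(design.y.mean() - X_full[:, keep].mean(axis=0) @ beta)
    fitted_means = {}
    c_effects = {}
    for g in uniq_c:
        m = countries == g
        xb = float(Xk_orig[m].mean(axis=0) @ beta)
        c_effects[g] = float(design.y[m].mean()) - xb - const
        fitted_means[g] = const + xb
    ce = np.array([c_effects[g] for g in uniq_c])
    fm = np.array([fitted_means[g] for g in uniq_c])
    if ce.std() > 0 and fm.std() > 0:
        corr_fe = float(np.corrcoef(ce, fm)[0, 1])
    else:
        corr_fe = float("nan")

    f_stat = (r2 / k) / ((1.0 - r2) / df_resid) if r2 < 1.0 else float("inf")

    # the reference (earliest) period carries an explicit zero effect so that
    # serialized fits round-trip without reconstruction
    params = {"const": const, f"period_{int(uniq_p[0])}": 0.0}
    std_errors: dict[str, float] = {}
    p_values: dict[str, float] = {}
    period_effects = {int(uniq_p[0]): 0.0}
    for nm, b, s, p in zip(kept_names, beta, se, pvals):
        params[nm] = float(b)
        std_errors[nm] = float(s)
        p_values[nm] = float(p)
        if nm.startswith("period_"):
            period_effects[int(nm.split("_", 1)[1])] = float(b)
    return CurveFit(
        code=design.code,
        method="panel_fe",
        params=params,
        std_errors=std_errors,
        p_values=p_values,
        dropped=tuple(dropped),
        n_obs=n,
        r2=r2,
        rmse=rmse,
        f_stat=f_stat,
        corr_fe=corr_fe,
        period_effects=period_effects,
    )


def fit_cross_section(design: PanelDesign) -> CurveFit:
    """Cross-sectional OLS with HC1 heteroskedasticity-robust errors.

    Region dummies are retained (AFR reference); all-zero dummy columns
    (empty categories) are dropped and recorded. F is the overall
    regression F statistic.
    """
    if design.method_tag != "cross_section":
        raise ValueError("design was not assembled for cross_section")
    n = design.n_obs
    names = ["const"] + design.columns
    X_full = np.hstack([np.ones((n, 1)), design.X])

    zero = np.linalg.norm(X_full, axis=0) == 0.0
    dropped = [nm for nm, z in zip(names, zero) if z]
    idx_alive = np.flatnonzero(~zero)
    keep_rel, rank_dropped = _greedy_rank_keep(
        X_full[:, idx_alive], [names[i] for i in idx_alive]
    )
    dropped += rank_dropped
    if dropped:
        logger.info("fit %s: dropped empty/collinear column(s): %s",
                    design.code, dropped)
    keep = idx_alive[keep_rel]
    kept_names = [names[i] for i in keep]
    Xk = X_full[:, keep]
    k = Xk.shape[1]
    if n < k + 1:
        raise DegenerateDesignError(
            f"indicator {design.code}: {n} row(s) for {k} coefficient(s)"
        )

    beta, *_ = np.linalg.lstsq(Xk, design.y, rcond=None)
    u = design.y - Xk @ beta
    ssr = float(u @ u)
    sst = float(((design.y - design.y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    df_resid = n - k
    rmse = float(np.sqrt(ssr / df_resid))

    bread = np.linalg.inv(Xk.T @ Xk)
    meat = Xk.T @ (Xk * (u ** 2)[:, None])
    V = (n / df_resid) * bread @ meat @ bread  # HC1
    se = np.sqrt(np.diag(V))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)

    k_slopes = k - 1 if "const" in kept_names else k
    if k_slopes > 0 and r2 < 1.0:
        f_stat = (r2 / k_slopes) / ((1.0 - r2) / df_resid)
    else:
        f_stat = float("inf") if r2 >= 1.0 else float("nan")

    params = {nm: float(b) for nm, b in zip(kept_names, beta)}
    return CurveFit(
        code=design.code,
        method="cross_section",
        params=params,
        std_errors={nm: float(s) for nm, s in zip(kept_names, se)},
        p_values={nm: float(p) for nm, p in zip(kept_names, pvals)},
        dropped=tuple(dropped),
        n_obs=n,
        r2=r2,
        rmse=rmse,
        f_stat=f_stat,
        corr_fe=None,
        period_effects=None,
    )


# ---------------------------------------------------------------------------
# method choice, gate, convenience drivers
# ---------------------------------------------------------------------------

def choose_method(registry: ThemeRegistry, code: str, obs_p: pd.DataFrame) -> str:
    """Pick the estimation regime for *code* given the data at hand.

    Panel estimation requires both registry eligibility (an MDG-era,
    multi-period series) and at least two populated periods in the data;
    otherwise the cross-sectional regime is used.
    """
    meta = registry.meta(code)
    n_periods = obs_p.loc[obs_p["code"] == code, "period"].nunique()
    if meta.panel_eligible and n_periods >= 2:
        return "panel_fe"
    return "cross_section"


def significance_gate(fit: CurveFit, alpha: float = 0.05) -> bool:
    """True iff the GDPpc elasticity is significant: p(b1) < alpha, strictly."""
    if "ln_gdp_pc" not in fit.params or "ln_gdp_pc" not in fit.p_values:
        raise GateError(f"fit for {fit.code} has no GDPpc term to gate on")
    p = fit.p_values["ln_gdp_pc"]
    if not np.isfinite(p):
        raise GateError(f"fit for {fit.code} has no usable p-value for GDPpc")
    return bool(p < alpha)


def fit_indicator(
    obs_p: pd.DataFrame,
    cov_p: pd.DataFrame,
    registry: ThemeRegistry,
    code: str,
    method_tag: str | None = None,
) -> CurveFit:
    """Build the design for *code* and fit it under the appropriate regime."""
    tag = method_tag or choose_method(registry, code, obs_p)
    design = build_design(obs_p, cov_p, registry, code, tag)
    if tag == "panel_fe":
        return fit_panel_fe(design)
    return fit_cross_section(design)


def fit_all(
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    registry: ThemeRegistry,
    width: int = 5,
    anchor: int = 2000,
) -> dict[str, CurveFit]:
    """Period-average the panels and fit every registry indicator present."""
    obs_p, cov_p = period_average(obs, cov, width=width, anchor=anchor)
    fits: dict[str, CurveFit] = {}
    for code in registry.codes:
        if code not in set(obs_p["code"]):
            continue
        try:
            fits[code] = fit_indicator(obs_p, cov_p, registry, code)
        except DegenerateDesignError as err:
            logger.warning("skipping %s: %s", code, err)
    return fits


# ---------------------------------------------------------------------------
# printed coefficient table
# ---------------------------------------------------------------------------

def load_printed_curves() -> dict[str, CurveFit]:
    """Load the transcription of the published coefficient table.

    Significance markers are encoded as representative p-value bounds
    (``***`` -> 1e-4, ``**`` -> 5e-3, ``*`` -> 2.5e-2, unstarred -> 0.5) so
    that :func:`significance_gate` reproduces the printed starring at the
    0.05 level. Regional-dummy coefficients are not transcribed.
    """
    text = (
        resources.files("sdgcurves.data").joinpath("printed_curves.csv").read_text("utf-8")
    )
    fits: dict[str, CurveFit] = {}
    for row in csv.DictReader(text.splitlines()):
        code = row["code"]
        params = {
            "const": float(row["const"]),
            "ln_gdp_pc": float(row["beta_gdp"]),
            "gini": float(row["beta_gini"]),
            "health_exp": float(row["beta_health"]),
        }
        p_values = {
            "ln_gdp_pc": _STARS_P[int(row["stars_gdp"])],
            "gini": _STARS_P[int(row["stars_gini"])],
            "health_exp": _STARS_P[int(row["stars_health"])],
            "const": _STARS_P[int(row["stars_const"])],
        }
        corr = float(row["corr_fe"]) if row["corr_fe"] else None
        fits[code] = CurveFit(
            code=code,
            method="printed",
            params=params,
            p_values=p_values,
            n_obs=int(row["n_obs"]),
            r2=float(row["r2"]),
            rmse=float(row["rmse"]),
            f_stat=float(row["f_stat"]),
            corr_fe=corr,
        )
    return fits


# ---------------------------------------------------------------------------
# fit table (de)serialization
# ---------------------------------------------------------------------------

def fits_to_frame(fits: dict[str, CurveFit]) -> pd.DataFrame:
    """Flatten fits into the long output schema (one row per term, plus a
    ``<summary>`` row per fit carrying the fit statistics)."""
    rows = []
    for code in sorted(fits):
        f = fits[code]
        for term in f.params:
            rows.append({
                "code": code, "method": f.method, "term": term,
                "estimate": f.params[term],
                "std_error": f.std_errors.get(term, np.nan),
                "p_value": f.p_values.get(term, np.nan),
                "dropped": False,
                "n_obs": np.nan, "r2": np.nan, "rmse": np.nan,
                "f_stat": np.nan, "corr_fe": np.nan,
            })
        for term in f.dropped:
            rows.append({
                "code": code, "method": f.method, "term": term,
                "estimate": np.nan, "std_error": np.nan, "p_value": np.nan,
                "dropped": True,
                "n_obs": np.nan, "r2": np.nan, "rmse": np.nan,
                "f_stat": np.nan, "corr_fe": np.nan,
            })
        rows.append({
            "code": code, "method": f.method, "term": "<summary>",
            "estimate": np.nan, "std_error": np.nan, "p_value": np.nan,
            "dropped": False,
            "n_obs": f.n_obs, "r2": f.r2, "rmse": f.rmse,
            "f_stat": f.f_stat,
            "corr_fe": np.nan if f.corr_fe is None else f.corr_fe,
        })
    return pd.DataFrame(rows)


def fits_from_frame(df: pd.DataFrame) -> dict[str, CurveFit]:
    """Rebuild :class:`CurveFit` objects from the long fit table."""
    fits: dict[str, CurveFit] = {}
    for code, sub in df.groupby("code"):
        method = str(sub["method"].iloc[0])
        params: dict[str, float] = {}
        std_errors: dict[str, float] = {}
        p_values: dict[str, float] = {}
        dropped: list[str] = []
        period_effects: dict[int, float] | None = None
        summary = sub.loc[sub["term"] == "<summary>"].iloc[0]
        for _, row in sub.iterrows():
            term = str(row["term"])
            if term == "<summary>":
                continue
            if bool(row["dropped"]):
                dropped.append(term)
                continue
            params[term] = float(row["estimate"])
            if np.isfinite(row["std_error"]):
                std_errors[term] = float(row["std_error"])
            if np.isfinite(row["p_value"]):
                p_values[term] = float(row["p_value"])
            if term.startswith("period_"):
                period_effects = period_effects or {}
                period_effects[int(term.split("_", 1)[1])] = float(row["estimate"])
        corr = float(summary["corr_fe"]) if np.isfinite(summary["corr_fe"]) else None
        fits[str(code)] = CurveFit(
            code=str(code),
            method=method,
            params=params,
            std_errors=std_errors,
            p_values=p_values,
            dropped=tuple(dropped),
            n_obs=int(summary["n_obs"]),
            r2=float(summary["r2"]),
            rmse=float(summary["rmse"]),
            f_stat=float(summary["f_stat"]),
            corr_fe=corr,
            period_effects=period_effects,
        )
    return fits
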