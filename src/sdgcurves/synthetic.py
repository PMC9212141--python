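"""Synthetic panel generator with known ground truth.

Emulates the structural data-generating process behind the global evolution
curves: for country *i* in year *t*,

    ln(value)_it = alpha + b_gdp * ln(gdp_pc)_it + b_health * health_exp_it
                   + b_gini * gini_it + b_region[region(i)]
                   + c_i + p_t + eps_it

with mean-zero country effects ``c_i``, period effects ``p_t`` and i.i.d.
noise ``eps_it``. Log GDP per capita follows a per-country random walk with
drift so that within-country temporal variation identifies the panel
estimator; Gini and public-health-expenditure paths are stationary around
country-specific bases; regions are assigned round-robin over the six WHO
regions so every regional dummy is estimable in cross-sections.

The generator also produces IMF-style growth-scenario tables (annual
GDP-per-capita growth fractions to a horizon year), including degenerate
all-zero and contraction scenarios on demand.

Everything is driven by a single seeded :class:`numpy.random.Generator`
stream, so identical specs yield identical panels. The returned *truth*
record carries every drawn effect and parameter, serving as the oracle for
parameter-recovery experiments. The generator mimics only this structural
model, not the marginal distributions of real WHO series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import WHO_REGIONS

__all__ = ["SyntheticSpec", "generate_panel", "generate_growth_scenarios"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic data-generating process.

    Defaults correspond to a mortality-like indicator: GDP elasticity
    -1.05 (the printed maternal-mortality slope), small Gini and
    health-expenditure effects with the magnitudes seen in the published
    curves, 60 countries observed over six 5-year periods (1990-2019),
    and noise of the order of the published root-mean-square errors.
    """

    n_countries: int = 60
    years: tuple[int, int] = (1990, 2019)
    period_width: int = 5
    obs_per_period: int = 1  # observation years per period bin, from the anchor
    regions: Mapping[str, str] | None = None  # country -> WHO region; default round-robin
    code: str = "311"
    direction: int = -1

    alpha: float = 13.7
    beta_gdp: float = -1.05
    beta_health: float = -0.03
    beta_gini: float = 0.01
    beta_region: Mapping[str, float] = field(
        default_factory=lambda: {
            "AFR": 0.0, "AMR": -0.2, "EMR": 0.1, "EUR": -0.3, "SEAR": 0.15, "WPR": -0.1,
        }
    )

    sigma_country: float = 0.3
    sigma_time: float = 0.05
    sigma_eps: float = 0.1

    # covariate model
    ln_gdp0_mean: float = 8.0
    ln_gdp0_sd: float = 1.2
    gdp_drift: float = 0.02  # per year, on log GDPpc
    gdp_vol: float = 0.03  # per sqrt(year)
    gini_range: tuple[float, float] = (28.0, 55.0)
    health_range: tuple[float, float] = (2.0, 10.0)

    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        if self.period_width < 1:
            raise ValueError("period_width must be >= 1")
        if not 1 <= self.obs_per_period <= self.period_width:
            raise ValueError("obs_per_period must be in [1, period_width]")
        for name in ("sigma_country", "sigma_time", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.beta_region.get("AFR", 0.0) != 0.0:
            raise ValueError("reference-region (AFR) coefficient must be 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def period_anchors(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1, self.period_width))


def generate_panel(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic (observation, covariate) panel pair.

    Returns
    -------
    observations:
        Long table ``country, year, code, value``.
    covariates:
        Long table ``country, year, gdp_pc, gini, health_exp, region``.
    truth:
        Dict with every parameter and drawn effect: ``country_effects``
        (country -> c_i), ``period_effects`` (anchor year -> p_t), the
        coefficient values, and the noiseless linear predictor per record
        under ``ln_mean``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    countries = [f"C{i + 1:03d}" for i in range(spec.n_countries)]
    if spec.regions is not None:
        regions = {c: spec.regions[c] for c in countries}
    else:
        regions = {c: WHO_REGIONS[i % len(WHO_REGIONS)] for i, c in enumerate(countries)}

    anchors = spec.period_anchors
    c_eff = dict(zip(countries, rng.normal(0.0, spec.sigma_country, spec.n_countries)))
    p_eff = dict(zip(anchors, rng.normal(0.0, spec.sigma_time, len(anchors))))

    # per-country covariate paths, one draw per period, constant within a bin
    ln_gdp0 = rng.normal(spec.ln_gdp0_mean, spec.ln_gdp0_sd, spec.n_countries)
    gini0 = rng.uniform(*spec.gini_range, spec.n_countries)
    health0 = rng.uniform(*spec.health_range, spec.n_countries)

    obs_rows: list[dict] = []
    cov_rows: list[dict] = []
    ln_mean: dict[tuple[str, int], float] = {}
    w = spec.period_width
    for ci, country in enumerate(countries):
        ln_gdp = ln_gdp0[ci]
        gini = gini0[ci]
        health = health0[ci]
        for anchor in anchors:
            if anchor != anchors[0]:
                ln_gdp += spec.gdp_drift * w + rng.normal(0.0, spec.gdp_vol * np.sqrt(w))
                gini = float(np.clip(gini + rng.normal(0.0, 1.0), 20.0, 65.0))
                health = float(np.clip(health + rng.normal(0.0, 0.3), 0.5, 15.0))
            gdp_pc = float(np.exp(ln_gdp))
            mu = (
                spec.alpha
                + spec.beta_gdp * ln_gdp
                + spec.beta_health * health
                + spec.beta_gini * gini
                + spec.beta_region.get(regions[country], 0.0)
                + c_eff[country]
                + p_eff[anchor]
            )
            for j in range(spec.obs_per_period):
                year = anchor + j
                eps = rng.normal(0.0, spec.sigma_eps) if spec.sigma_eps > 0 else 0.0
                obs_rows.append(
                    {"country": country, "year": year, "code": spec.code,
                     "value": float(np.exp(mu + eps))}
                )
                cov_rows.append(
                    {"country": country, "year": year, "gdp_pc": gdp_pc,
                     "gini": gini, "health_exp": health, "region": regions[country]}
                )
                ln_mean[(country, year)] = mu

    obs = pd.DataFrame(obs_rows)
    cov = pd.DataFrame(cov_rows)
    truth = {
        "alpha": spec.alpha,
        "beta_gdp": spec.beta_gdp,
        "beta_health": spec.beta_health,
        "beta_gini": spec.beta_gini,
        "beta_region": dict(spec.beta_region),
        "country_effects": c_eff,
        "period_effects": p_eff,
        "regions": regions,
        "ln_mean": ln_mean,
        "spec": spec,
    }
    return obs, cov, truth


def generate_growth_scenarios(
    countries: Sequence[str],
    baseline_year: int = 2019,
    end_year: int = 2030,
    rate_range: tuple[float, float] = (-0.02, 0.08),
    seed: int = 0,
    baseline_gdp_pc: Mapping[str, float] | None = None,
    kind: str = "random",
) -> pd.DataFrame:
    """Draw per-country annual GDP-per-capita growth scenarios.

    ``kind`` selects the scenario family: ``"random"`` draws each annual
    rate uniformly from *rate_range*; ``"zero"`` sets every rate to 0 (the
    no-growth degenerate case); ``"contraction"`` draws uniformly from the
    negative range (-4%, -0.5%). Baseline GDP per capita is taken from
    *baseline_gdp_pc* when given, otherwise drawn log-normally.
    """
    if end_year <= baseline_year:
        raise ValueError("horizon is empty: end_year must exceed baseline_year")
    if kind not in {"random", "zero", "contraction"}:
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng(seed)
    horizon = list(range(baseline_year + 1, end_year + 1))
    rows = []
    for country in countries:
        if kind == "zero":
            rates = np.zeros(len(horizon))
        elif kind == "contraction":
            rates = rng.uniform(-0.04, -0.005, len(horizon))
        else:
            rates = rng.uniform(rate_range[0], rate_range[1], len(horizon))
        if baseline_gdp_pc is not None:
            base = float(baseline_gdp_pc[country])
        else:
            base = float(np.exp(rng.normal(9.0, 1.0)))
        row = {"country": country, "baseline_year": baseline_year,
               "baseline_gdp_pc": base}
        row.update({f"g{y}": float(r) for y, r in zip(horizon, rates)})
        rows.append(row)
    return pd.DataFrame(rows)
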