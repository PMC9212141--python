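"""Estimator correctness: binning oracles, LSDV equivalence, independent
statsmodels cross-checks, method choice and the significance gate."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import random_small_panel
from sdgcurves.estimation import (
    CurveFit,
    DegenerateDesignError,
    GateError,
    build_design,
    choose_method,
    fit_cross_section,
    fit_panel_fe,
    fits_from_frame,
    fits_to_frame,
    load_printed_curves,
    period_average,
    significance_gate,
)
from sdgcurves.io import WHO_REGIONS
from sdgcurves.registry import RegistryError
from sdgcurves.synthetic import SyntheticSpec, generate_panel


# ---------------------------------------------------------------------------
# period averaging
# ---------------------------------------------------------------------------

def test_period_average_width_one_is_identity(registry):
    obs, cov, _ = generate_panel(SyntheticSpec(n_countries=5, seed=0))
    op, cp = period_average(obs, cov, width=1)
    merged = obs.rename(columns={"year": "period"}).merge(
        op, on=["country", "period", "code"], suffixes=("", "_b")
    )
    np.testing.assert_allclose(merged["value"], merged["value_b"])


def test_period_average_arithmetic_mean():
    obs = pd.DataFrame({
        "country": ["X", "X"], "year": [2015, 2018],
        "code": ["321", "321"], "value": [10.0, 20.0],
    })
    cov = pd.DataFrame({
        "country": ["X", "X"], "year": [2015, 2018],
        "gdp_pc": [1000.0, 2000.0], "gini": [40.0, 42.0],
        "health_exp": [3.0, 5.0], "region": ["AMR", "AMR"],
    })
    op, cp = period_average(obs, cov, width=5, anchor=2000)
    assert list(op["period"]) == [2015]
    assert op["value"].iloc[0] == 15.0
    assert cp["gdp_pc"].iloc[0] == 1500.0


def test_period_average_matches_brute_force_on_thinned_panel():
    rng = np.random.default_rng(12)
    obs, cov, _ = generate_panel(
        SyntheticSpec(n_countries=8, obs_per_period=5, seed=12)
    )
    obs = obs.sample(frac=0.6, random_state=3).reset_index(drop=True)
    op, _ = period_average(obs, cov, width=5, anchor=2000)
    for _, row in op.iterrows():
        members = [
            v for c, y, v in zip(obs["country"], obs["year"], obs["value"])
            if c == row["country"] and row["period"] <= y < row["period"] + 5
        ]
        assert members
        assert abs(row["value"] - sum(members) / len(members)) < 1e-12


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def test_build_design_drops_nonpositive_values(registry):
    rng = np.random.default_rng(1)
    obs, cov = random_small_panel(rng, n_countries=6, n_periods=3)
    obs.loc[0, "value"] = 0.0
    op, cp = period_average(obs, cov, width=5)
    d = build_design(op, cp, registry, "311", "panel_fe")
    assert d.n_dropped == 1
    assert d.n_obs == len(obs) - 1


def test_build_design_six_regions_give_five_dummies(registry):
    rng = np.random.default_rng(2)
    obs, cov = random_small_panel(rng, n_countries=6, n_periods=3)
    d = build_design(*period_average(obs, cov, 5), registry, "311", "panel_fe")
    dummy_cols = [c for c in d.columns if c.startswith("region_")]
    assert dummy_cols == [f"region_{r}" for r in WHO_REGIONS[1:]]
    # AFR rows (country C00) carry all-zero dummies
    afr = d.X[d.country == "C00"][:, [d.columns.index(c) for c in dummy_cols]]
    assert (afr == 0).all()


def test_build_design_reproduces_generator_design(registry):
    spec = SyntheticSpec(n_countries=6, sigma_eps=0, seed=8)
    obs, cov, truth = generate_panel(spec)
    op, cp = period_average(obs, cov, width=5, anchor=2000)
    d = build_design(op, cp, registry, "311", "panel_fe")
    merged = obs.merge(cov, on=["country", "year"]).sort_values(["country", "year"])
    np.testing.assert_allclose(d.y, np.log(merged["value"]), atol=1e-12)
    j = d.columns.index("ln_gdp_pc")
    np.testing.assert_allclose(d.X[:, j], np.log(merged["gdp_pc"]), atol=1e-12)


def test_build_design_unknown_code_raises(registry):
    rng = np.random.default_rng(3)
    obs, cov = random_small_panel(rng)
    with pytest.raises(RegistryError, match="999"):
        build_design(*period_average(obs, cov, 5), registry, "999", "panel_fe")


# ---------------------------------------------------------------------------
# panel fixed effects
# ---------------------------------------------------------------------------

def _lsdv_oracle(design):
    """Least-squares with explicit country and period dummy columns."""
    struct = [c for c in design.columns if not c.startswith("region_")]
    idx = [design.columns.index(c) for c in struct]
    Xs = design.X[:, idx]
    periods = np.sort(np.unique(design.period))
    P = np.column_stack([(design.period == p).astype(float) for p in periods[1:]])
    countries = np.unique(design.country)
    C = np.column_stack([(design.country == c).astype(float) for c in countries])
    X = np.hstack([Xs, P, C])
    beta, *_ = np.linalg.lstsq(X, design.y, rcond=None)
    names = struct + [f"period_{p}" for p in periods[1:]]
    return dict(zip(names, beta[: len(names)]))


def test_within_estimator_matches_lsdv_on_50_random_panels(registry):
    rng = np.random.default_rng(99)
    for _ in range(50):
        obs, cov = random_small_panel(rng)
        op, cp = period_average(obs, cov, width=5)
        design = build_design(op, cp, registry, "311", "panel_fe")
        fit = fit_panel_fe(design)
        oracle = _lsdv_oracle(design)
        for term, b in oracle.items():
            assert abs(fit.params[term] - b) < 1e-8, term
        # region dummies always collinear with country effects
        assert {c for c in design.columns if c.startswith("region_")} <= set(fit.dropped)


def test_panel_cluster_se_matches_statsmodels(registry):
    obs, cov, _ = generate_panel(SyntheticSpec(n_countries=30, seed=21))
    op, cp = period_average(obs, cov, width=5)
    design = build_design(op, cp, registry, "311", "panel_fe")
    fit = fit_panel_fe(design)

    struct = [c for c in design.columns if not c.startswith("region_")]
    idx = [design.columns.index(c) for c in struct]
    periods = np.sort(np.unique(design.period))
    P = np.column_stack([(design.period == p).astype(float) for p in periods[1:]])
    countries = np.unique(design.country)
    C = np.column_stack([(design.country == c).astype(float) for c in countries])
    X = np.hstack([design.X[:, idx], P, C])
    res = sm.OLS(design.y, X).fit(
        cov_type="cluster", cov_kwds={"groups": design.country}
    )
    for j, term in enumerate(struct):
        assert abs(fit.params[term] - res.params[j]) < 1e-8
        assert abs(fit.std_errors[term] - res.bse[j]) < 1e-6 * max(1, res.bse[j])


def test_panel_requires_two_periods_and_countries(registry):
    rng = np.random.default_rng(5)
    obs, cov = random_small_panel(rng, n_countries=12, n_periods=1)
    op, cp = period_average(obs, cov, width=5)
    design = build_design(op, cp, registry, "311", "panel_fe")
    with pytest.raises(DegenerateDesignError):
        fit_panel_fe(design)


def test_scale_equivariance_only_constant_moves(registry):
    rng = np.random.default_rng(6)
    obs, cov = random_small_panel(rng, n_countries=8, n_periods=4)
    op, cp = period_average(obs, cov, width=5)
    f1 = fit_panel_fe(build_design(op, cp, registry, "311", "panel_fe"))
    obs2 = obs.assign(value=obs["value"] * 1000.0)
    op2, _ = period_average(obs2, cov, width=5)
    f2 = fit_panel_fe(build_design(op2, cp, registry, "311", "panel_fe"))
    for term in f1.params:
        if term == "const":
            assert abs(f2.params[term] - f1.params[term] - np.log(1000.0)) < 1e-8
        else:
            assert abs(f2.params[term] - f1.params[term]) < 1e-8


def test_elasticity_semantics_response_ratio_for_gdp_doubling(registry):
    from sdgcurves.gap import counterfactual

    spec = SyntheticSpec(sigma_eps=0, sigma_country=0, sigma_time=0, seed=4)
    obs, cov, _ = generate_panel(spec)
    op, cp = period_average(obs, cov, width=5)
    fit = fit_panel_fe(build_design(op, cp, registry, "311", "panel_fe"))
    lo = counterfactual(fit, 5000.0, 5.0, 40.0, "AFR")
    hi = counterfactual(fit, 10000.0, 5.0, 40.0, "AFR")
    assert abs(hi / lo - 2.0 ** fit.beta_gdp) < 1e-9


# ---------------------------------------------------------------------------
# cross-section
# ---------------------------------------------------------------------------

def test_cross_section_matches_statsmodels_hc1(registry):
    rng = np.random.default_rng(31)
    obs, cov = random_small_panel(rng, n_countries=40, n_periods=1)
    op, cp = period_average(obs, cov, width=5)
    design = build_design(op, cp, registry, "311", "cross_section")
    fit = fit_cross_section(design)
    X = sm.add_constant(design.X)
    robust = sm.OLS(design.y, X).fit(cov_type="HC1")
    classical = sm.OLS(design.y, X).fit()
    names = ["const"] + design.columns
    for j, term in enumerate(names):
        assert abs(fit.params[term] - robust.params[j]) < 1e-8
        assert abs(fit.std_errors[term] - robust.bse[j]) < 1e-8
    assert abs(fit.r2 - classical.rsquared) < 1e-10
    # overall F is the classical regression F, not the robust Wald form
    assert abs(fit.f_stat - classical.fvalue) < 1e-6


def test_cross_section_noise_free_is_perfect_fit(registry):
    spec = SyntheticSpec(n_countries=20, sigma_eps=0, sigma_country=0,
                         sigma_time=0, seed=13)
    obs, cov, _ = generate_panel(spec)
    op, cp = period_average(obs, cov, width=5)
    fit = fit_cross_section(build_design(op, cp, registry, "311", "cross_section"))
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)
    assert fit.rmse == pytest.approx(0.0, abs=1e-8)


def test_cross_section_drops_empty_region_dummy(registry):
    rng = np.random.default_rng(41)
    n = 12
    regions = ["AFR", "AMR", "EMR", "EUR"]  # SEAR and WPR unrepresented
    obs = pd.DataFrame({
        "country": [f"C{i:02d}" for i in range(n)], "year": 2016,
        "code": "311", "value": rng.uniform(5, 50, n),
    })
    cov = pd.DataFrame({
        "country": obs["country"], "year": 2016,
        "gdp_pc": rng.uniform(1000, 50000, n), "gini": rng.uniform(25, 60, n),
        "health_exp": rng.uniform(1, 12, n),
        "region": [regions[i % 4] for i in range(n)],
    })
    op, cp = period_average(obs, cov, width=5)
    design = build_design(op, cp, registry, "311", "cross_section")
    fit = fit_cross_section(design)
    assert "region_SEAR" in fit.dropped and "region_WPR" in fit.dropped
    assert "region_SEAR" not in fit.params


def test_robust_and_classical_se_agree_under_homoskedasticity(registry):
    """With homoskedastic noise and large N, HC1 and classical standard
    errors for the GDPpc slope agree within 10% on average (200 replicates)."""
    rng = np.random.default_rng(77)
    ratios = []
    for r in range(200):
        n = 150
        x = rng.normal(8.5, 1.0, n)
        y = 2.0 - 0.8 * x + rng.normal(0, 0.3, n)
        obs = pd.DataFrame({
            "country": [f"C{i:03d}" for i in range(n)],
            "year": 2016, "code": "352", "value": np.exp(y),
        })
        cov = pd.DataFrame({
            "country": obs["country"], "year": 2016,
            "gdp_pc": np.exp(x), "gini": rng.uniform(25, 60, n),
            "health_exp": rng.uniform(1, 12, n),
            "region": [WHO_REGIONS[i % 6] for i in range(n)],
        })
        op, cp = period_average(obs, cov, width=5)
        design = build_design(op, cp, registry, "352", "cross_section")
        fit = fit_cross_section(design)
        X = sm.add_constant(design.X)
        classical = sm.OLS(design.y, X).fit().bse[1]
        ratios.append(fit.std_errors["ln_gdp_pc"] / classical)
    assert abs(np.mean(ratios) - 1.0) < 0.1


# ---------------------------------------------------------------------------
# method choice and gate
# ---------------------------------------------------------------------------

def test_choose_method_panel_for_mdg_series(registry):
    obs_p = pd.DataFrame({
        "country": ["A"] * 4, "period": [2000, 2005, 2010, 2015],
        "code": ["311"] * 4, "value": [1.0] * 4,
    })
    assert choose_method(registry, "311", obs_p) == "panel_fe"


def test_choose_method_cross_section_for_sdg_era_indicator(registry):
    obs_p = pd.DataFrame({
        "country": ["A"], "period": [2015], "code": ["352"], "value": [1.0],
    })
    assert choose_method(registry, "352", obs_p) == "cross_section"


def test_choose_method_falls_back_with_single_period(registry):
    obs_p = pd.DataFrame({
        "country": ["A", "B"], "period": [2015, 2015],
        "code": ["311", "311"], "value": [1.0, 2.0],
    })
    assert choose_method(registry, "311", obs_p) == "cross_section"


def test_gate_strict_boundary_and_vacuous_level():
    fit = CurveFit(code="x", method="printed",
                   params={"ln_gdp_pc": -1.0}, p_values={"ln_gdp_pc": 0.05})
    assert significance_gate(fit, 0.05) is False  # strict inequality
    assert significance_gate(fit, 1.0) is True
    bad = CurveFit(code="y", method="printed", params={}, p_values={})
    with pytest.raises(GateError):
        significance_gate(bad)


def test_printed_table_gate_passes_exactly_32_of_38(printed):
    assert len(printed) == 38
    passed = [c for c, f in printed.items() if significance_gate(f, 0.05)]
    assert len(passed) == 32
    failed = set(printed) - set(passed)
    assert failed == {"3b1a", "3b1b", "3b1c", "331", "3a1", "17192"}


def test_printed_curves_elasticity_values(printed):
    assert printed["311"].beta_gdp == pytest.approx(-1.0502)
    assert printed["335"].beta_gdp == pytest.approx(-2.3991)
    assert printed["352"].beta_gdp == pytest.approx(0.2479)


# ---------------------------------------------------------------------------
# serialization round-trip
# ---------------------------------------------------------------------------

def test_fits_roundtrip_through_long_frame(registry):
    obs, cov, _ = generate_panel(SyntheticSpec(n_countries=10, seed=55))
    op, cp = period_average(obs, cov, width=5)
    fit = fit_panel_fe(build_design(op, cp, registry, "311", "panel_fe"))
    frame = fits_to_frame({"311": fit})
    back = fits_from_frame(frame)["311"]
    assert back.method == fit.method
    assert set(back.params) == set(fit.params)
    for term in fit.params:
        assert back.params[term] == pytest.approx(fit.params[term])
    assert set(back.dropped) == set(fit.dropped)
    assert back.period_effects == pytest.approx(fit.period_effects)
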