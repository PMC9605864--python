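"""Sectoral damage functions: closed-form fits, monetization identities,
interpolation schemes, sampling distributions."""

import numpy as np
import pytest

from sccarbon import damages as D
from sccarbon import scenarios as S


@pytest.fixture(scope="module")
def flat_draw():
    """Two-country draw with constant, hand-set socioeconomics."""
    years = S.YEARS.copy()
    n = (2, years.size)
    return S.ScenarioDraw(
        years=years,
        countries=["AAA", "AAB"],
        population=np.full(n, 1_000_000.0),
        gdppc=np.full(n, 63_000.0),
        mortality_rate=np.full(n, 0.001),
        co2=np.zeros(years.size),
        ch4=np.zeros(years.size),
        n2o=np.zeros(years.size),
    )


# ---------------------------------------------------------------- energy


def test_through_origin_fit_closed_form():
    beta = D.fit_energy_coefficients({0: [(1, 0.002), (2, 0.006), (3, 0.007)]})
    assert beta[0] == pytest.approx(0.035 / 14.0, abs=1e-15)


def test_through_origin_fit_exact_line():
    pts = [(t, 0.004 * t) for t in (0.5, 1.0, 2.5)]
    assert D.fit_energy_coefficients({0: pts})[0] == pytest.approx(0.004)


def test_through_origin_fit_recovers_known_beta():
    rng = np.random.default_rng(0)
    beta_true, n, sd = 0.003, 50, 0.0003
    x = rng.uniform(0.5, 4.0, n)
    y = beta_true * x + rng.normal(0, sd, n)
    beta_hat = D.fit_energy_coefficients({0: np.column_stack([x, y])})[0]
    se = sd / np.sqrt(np.sum(x**2))
    assert abs(beta_hat - beta_true) < 3 * se


def test_through_origin_fit_errors():
    with pytest.raises(ValueError, match="fit undefined"):
        D.fit_energy_coefficients({0: [(0.0, 0.1), (0.0, 0.2)]})
    with pytest.raises(ValueError, match=">= 2"):
        D.fit_energy_coefficients({0: [(1.0, 0.1)]})


def test_energy_damages_zero_at_zero_warming(flat_draw):
    T = np.zeros(flat_draw.years.size)
    out = D.energy_damages(flat_draw, T, D.DEFAULT_ENERGY_BETA, D.DamageParams())
    assert np.all(out.damages == 0.0)


def test_energy_fraction_arithmetic_and_gdp_homogeneity(flat_draw):
    params = D.DamageParams()
    beta = np.full(D.N_ENERGY_REGIONS, 0.005)
    T = np.full(flat_draw.years.size, 2.0)
    out = D.energy_damages(flat_draw, T, beta, params)
    gdp = flat_draw.population * flat_draw.gdppc
    np.testing.assert_allclose(out.damages / gdp, 0.01, rtol=1e-14)

    doubled = S.ScenarioDraw(
        **{
            **vars(flat_draw),
            "gdppc": flat_draw.gdppc * 2,
        }
    )
    out2 = D.energy_damages(doubled, T, beta, params)
    np.testing.assert_allclose(out2.damages, 2 * out.damages, rtol=1e-14)


def test_energy_region_aggregation_consistency(draw):
    """Summing country damages into regions equals computing at region level
    (the damage fraction is common within a region)."""
    params = D.DamageParams()
    T = np.linspace(0, 3, draw.years.size)
    out = D.energy_damages(draw, T, D.DEFAULT_ENERGY_BETA, params)
    maps = params.maps_for(len(draw.countries))["energy"]
    by_region = np.zeros((D.N_ENERGY_REGIONS, draw.years.size))
    np.add.at(by_region, maps, out.damages)
    gdp_region = np.zeros_like(by_region)
    np.add.at(gdp_region, maps, draw.population * draw.gdppc)
    direct = D.DEFAULT_ENERGY_BETA[:, None] * T[None, :] * gdp_region
    np.testing.assert_allclose(by_region, direct, rtol=1e-12)


# ------------------------------------------------------------- mortality


def test_mortality_beta_zero_se_is_point_estimate():
    p = D.DamageParams(mortality_beta_se=np.zeros(D.N_MORTALITY_REGIONS))
    np.testing.assert_array_equal(
        D.sample_mortality_beta(p, 3), p.mortality_beta_mean
    )


def test_mortality_beta_sampling_mean_and_reproducibility():
    p = D.DamageParams()
    n = 10_000
    draws = np.array([D.sample_mortality_beta(p, s) for s in range(n)])
    se = p.mortality_beta_se / np.sqrt(n)
    assert np.all(np.abs(draws.mean(axis=0) - p.mortality_beta_mean) < 3.5 * se)
    np.testing.assert_array_equal(
        D.sample_mortality_beta(p, 7), D.sample_mortality_beta(p, 7)
    )


def test_mortality_arithmetic_and_vsl(flat_draw):
    """beta=0.01/K at T=1.5K on 1,000 baseline deaths gives 15 excess
    deaths, valued at the US-reference VSL of $10.05M."""
    params = D.DamageParams()
    beta = np.full(D.N_MORTALITY_REGIONS, 0.01)
    T = np.full(flat_draw.years.size, 1.5)
    out = D.mortality_damages(flat_draw, T, beta, params)
    # baseline deaths per country-year: 1e6 * 0.001 = 1,000
    np.testing.assert_allclose(out.excess_deaths, 15.0, rtol=1e-14)
    np.testing.assert_allclose(
        out.damages / out.excess_deaths, 10.05e6, rtol=1e-14
    )


def test_vsl_income_scaling_linear_at_unit_elasticity():
    p = D.DamageParams()
    assert D.value_of_statistical_life(p.vsl_ref_gdppc, p) == pytest.approx(10.05e6)
    assert D.value_of_statistical_life(p.vsl_ref_gdppc / 2, p) == pytest.approx(
        5.025e6
    )


def test_mortality_monetization_identity(draw):
    p = D.DamageParams()
    beta = D.sample_mortality_beta(p, 0)
    T = np.linspace(0, 2.5, draw.years.size)
    out = D.mortality_damages(draw, T, beta, p)
    vsl = D.value_of_statistical_life(draw.gdppc, p)
    mask = out.excess_deaths != 0
    np.testing.assert_allclose(
        (out.damages / np.where(mask, out.excess_deaths, 1.0))[mask],
        vsl[mask],
        rtol=1e-12,
    )


def test_mortality_negative_rate_rejected(flat_draw):
    bad = S.ScenarioDraw(
        **{**vars(flat_draw), "mortality_rate": -flat_draw.mortality_rate}
    )
    with pytest.raises(ValueError, match="mortality rate"):
        D.mortality_damages(
            bad, np.ones(bad.years.size),
            np.zeros(D.N_MORTALITY_REGIONS), D.DamageParams(),
        )


# ------------------------------------------------------------ agriculture


def test_ag_weight_triangular_properties():
    n = 10_000
    vals = np.array([D.sample_ag_weight(s) for s in range(n)])
    assert np.all((vals >= 0) & (vals <= 1))
    se = vals.std(ddof=1) / np.sqrt(n)
    assert abs(vals.mean() - 0.5) < 3 * se
    # CDF at the mode of a symmetric triangular is 1/2
    frac = (vals <= 0.5).mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def test_ag_blend_anchor_cases():
    knots = D.default_ag_knots()
    np.testing.assert_array_equal(D.blend_ag_knots(knots, 0.5), knots[:, 1, :])
    np.testing.assert_allclose(
        D.blend_ag_knots(knots, 0.75),
        0.5 * (knots[:, 1, :] + knots[:, 2, :]),
        rtol=1e-15,
    )
    np.testing.assert_array_equal(D.blend_ag_knots(knots, 0.0), knots[:, 0, :])


def test_ag_cost_fraction_piecewise_linear():
    kv = np.array([[0.01, 0.03, 0.08]])
    T = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0])
    f = D.ag_cost_fraction(kv, T)[0]
    assert f[0] == 0.0
    assert f[1] == pytest.approx(0.005)  # origin-to-1K interpolation
    assert f[2] == pytest.approx(0.01)
    assert f[3] == pytest.approx(0.02)
    assert f[5] == pytest.approx(0.055)
    assert f[7] == pytest.approx(0.08 + (0.08 - 0.03))  # extended last slope


def test_ag_negative_temperature_clamped_with_warning():
    kv = np.array([[0.01, 0.03, 0.08]])
    with pytest.warns(UserWarning, match="clamped"):
        f = D.ag_cost_fraction(kv, np.array([-0.5, 1.0]))
    assert f[0, 0] == 0.0


def test_ag_base_year_identity(flat_draw):
    """With the 1990 income factor set to 1, AgPctCost is sigma * f(T)."""
    p = D.DamageParams(ag_1990_income_factor=1.0)
    T = np.full(flat_draw.years.size, 2.0)
    out = D.agriculture_damages(flat_draw, T, 0.5, p)
    maps = p.maps_for(2)["agriculture"]
    f2 = D.ag_cost_fraction(D.blend_ag_knots(p.ag_knots, 0.5), np.array([2.0]))
    # both countries have identical gdp; regional damages = sigma*f*GDP_region
    gdp_region = np.zeros((D.N_AG_REGIONS, 1))
    np.add.at(gdp_region, maps, (flat_draw.population * flat_draw.gdppc)[:, :1])
    expected = p.ag_sigma[:, None] * f2 * gdp_region
    np.testing.assert_allclose(out.damages[:, :1], expected, rtol=1e-12)


def test_ag_damages_can_be_negative(flat_draw):
    """The low parameterization admits beneficial warming effects."""
    p = D.DamageParams()
    T = np.full(flat_draw.years.size, 1.0)
    out = D.agriculture_damages(flat_draw, T, 0.0, p)
    assert out.damages.min() < 0.0


def test_all_sector_fractions_zero_at_zero_warming(flat_draw):
    T = np.zeros(flat_draw.years.size)
    p = D.DamageParams()
    for out in (
        D.energy_damages(flat_draw, T, D.DEFAULT_ENERGY_BETA, p),
        D.mortality_damages(flat_draw, T, p.mortality_beta_mean, p),
        D.agriculture_damages(flat_draw, T, 0.7, p),
    ):
        assert np.all(out.damages == 0.0)
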