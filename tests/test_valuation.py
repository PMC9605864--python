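"""Discounting, marginal damages, SC-CO2 aggregation and the Monte Carlo
orchestrator."""

import math

import numpy as np
import pytest
import sympy

from sccarbon import fixtures as F
from sccarbon import scenarios as S
from sccarbon import valuation as V
from sccarbon.climate import PulseSpec

YEARS = S.YEARS.copy()


def _flat_draw(gdppc=20_000.0, pop=1e7):
    n = (1, YEARS.size)
    return S.ScenarioDraw(
        years=YEARS.copy(),
        countries=["AAA"],
        population=np.full(n, pop),
        gdppc=np.full(n, gdppc),
        mortality_rate=np.full(n, 0.008),
        co2=np.zeros(YEARS.size),
        ch4=np.zeros(YEARS.size),
        n2o=np.zeros(YEARS.size),
    )


# ----------------------------------------------------------- consumption


def test_consumption_equals_gdppc_without_damages():
    d = _flat_draw()
    c, floored = V.consumption_path(d, np.zeros(YEARS.size))
    np.testing.assert_array_equal(c, d.world_gdppc())
    assert floored == 0


def test_consumption_scales_with_uniform_damage_share():
    d = _flat_draw()
    gdp = d.world_gdp()
    c, _ = V.consumption_path(d, 0.1 * gdp)
    np.testing.assert_allclose(c, 0.9 * d.world_gdppc(), rtol=1e-14)


def test_consumption_floor_binds_with_diagnostic():
    d = _flat_draw()
    c, floored = V.consumption_path(d, 2.0 * d.world_gdp())
    assert floored == YEARS.size
    assert np.all(c == 100.0)


# ------------------------------------------------------------------ SDF


def test_sdf_reduces_to_pure_time_preference_at_eta_zero():
    c = np.linspace(2e4, 8e4, YEARS.size)
    spec = V.DiscountSpec(rho=0.01, eta=0.0)
    sdf = V.sdf_path(c, spec, YEARS)
    np.testing.assert_allclose(
        sdf, (1.01) ** (-(YEARS - 2020)), rtol=1e-13
    )
    assert sdf[0] == 1.0


def test_sdf_constant_growth_closed_form():
    g = 0.015
    c = 2e4 * (1 + g) ** (YEARS - 2020)
    spec = V.DiscountSpec(rho=0.002, eta=1.24)
    sdf = V.sdf_path(c, spec, YEARS)
    t = YEARS - 2020
    np.testing.assert_allclose(
        sdf, (1.002) ** (-t.astype(float)) * (1 + g) ** (-1.24 * t), rtol=1e-12
    )


def test_sdf_high_precision_point_oracle():
    """SDF in 2030 at rho=0.2%, eta=1.24 under 1.5%/yr growth, checked
    against 50-digit arithmetic."""
    g = 0.015
    c = 2e4 * (1 + g) ** (YEARS - 2020)
    sdf = V.sdf_path(c, V.DiscountSpec(0.002, 1.24), YEARS)
    expected = sympy.N(
        1 / sympy.Rational(1002, 1000) ** 10
        * (sympy.Rational(1015, 1000) ** sympy.Float("-12.4", 50)),
        30,
    )
    assert sdf[10] == pytest.approx(float(expected), rel=1e-12)


# ------------------------------------------------- marginal damages / SCC


class _Slice:
    def __init__(self, series):
        self._series = np.asarray(series, dtype=float)

    def total(self):
        return self._series


def test_md_zero_for_identical_runs():
    base = {"energy": _Slice(np.ones(YEARS.size))}
    md = V.marginal_damage_path(base, base, PulseSpec())
    assert np.all(md["energy"] == 0.0)


def test_md_normalizes_by_pulse_mass_in_tco2():
    """The tC->tCO2 conversion (44/12) is applied exactly once."""
    diff = 7.0e6  # USD/yr damage difference
    base = {"energy": _Slice(np.zeros(YEARS.size))}
    pulsed = {"energy": _Slice(np.full(YEARS.size, diff))}
    pulse = PulseSpec(mass_mtc=0.1)
    md = V.marginal_damage_path(base, pulsed, pulse)["energy"]
    expected = diff / (0.1e6 * 44.0 / 12.0)
    np.testing.assert_allclose(md, expected, rtol=1e-14)


def test_md_sector_mismatch_rejected():
    with pytest.raises(ValueError, match="different sectors"):
        V.marginal_damage_path(
            {"energy": _Slice(np.zeros(3))}, {"coastal": _Slice(np.zeros(3))},
            PulseSpec(),
        )


def test_scc_hand_sum():
    """$1/tCO2 marginal damage for the first ten years, undiscounted: $10."""
    md = np.where(YEARS <= 2029, 1.0, 0.0)
    sdf = np.ones(YEARS.size)
    assert V.scc_from_draw(md, sdf) == 10.0
    assert V.scc_from_draw(md, 0.5 * sdf) == 5.0


def test_scc_matches_compensated_summation_oracle():
    rng = np.random.default_rng(1)
    md = rng.normal(0, 10, YEARS.size)
    sdf = np.exp(-0.02 * (YEARS - 2020))
    ours = V.scc_from_draw(md, sdf)
    terms = [float(m) * float(s) for m, s in zip(md, sdf)]
    rng.shuffle(terms)
    assert ours == pytest.approx(math.fsum(terms), rel=1e-9)


def test_scc_weakly_decreasing_in_rho():
    md = np.abs(np.sin(np.arange(YEARS.size)))  # nonnegative damages
    c = 2e4 * 1.01 ** (YEARS - 2020)
    last = np.inf
    for rho in (0.0, 0.002, 0.01, 0.03):
        scc = V.scc_from_draw(md, V.sdf_path(c, V.DiscountSpec(rho, 1.0), YEARS))
        assert scc <= last
        last = scc


# -------------------------------------------------------------- near-term


def test_near_term_rate_identities():
    c_flat = np.full(YEARS.size, 2e4)
    assert V.near_term_rate(
        V.DiscountSpec(0.007, 0.0), [c_flat], YEARS
    ) == pytest.approx(0.7)
    g = 0.015
    c = 2e4 * (1 + g) ** (YEARS - 2020)
    assert V.near_term_rate(
        V.DiscountSpec(0.005, 1.0), [c], YEARS
    ) == pytest.approx(2.0, abs=1e-9)


def test_near_term_rate_matches_per_draw_averaging_oracle():
    rng = np.random.default_rng(3)
    cs = [2e4 * np.exp(np.cumsum(rng.normal(0.01, 0.01, YEARS.size))) for _ in range(5)]
    spec = V.DiscountSpec(0.002, 1.24)
    ours = V.near_term_rate(spec, cs, YEARS)
    acc = []
    for c in cs:
        per_year = []
        for t in range(2021, 2031):
            i = t - 2020
            g_t = (c[i] / c[0]) ** (1.0 / i) - 1.0
            per_year.append(spec.rho + spec.eta * g_t)
        acc.append(np.mean(per_year))
    assert ours == pytest.approx(100 * np.mean(acc), rel=1e-12)


# --------------------------------------------------------------- deflator


def test_deflator_identity_and_roundtrip():
    assert V.to_2020_usd(123.4, 2020) == 123.4
    back = V.to_2020_usd(
        float(V.to_2020_usd(50.0, 2011)) * V.DEFAULT_DEFLATOR[2011], 2020
    )
    assert back == pytest.approx(50.0, rel=1e-12)


def test_deflator_toy_table():
    table = {2000: 0.5, 2020: 1.0}
    assert V.to_2020_usd(10.0, 2000, table) == 20.0
    with pytest.raises(KeyError):
        V.to_2020_usd(1.0, 1999, table)


def test_packaged_discount_pairs():
    spec = V.discount_spec_for_rate(2.0)
    assert (spec.rho, spec.eta) == (0.002, 1.24)
    assert V.discount_spec_for_rate(1.5).eta == 1.02
    with pytest.raises(ValueError, match="not packaged"):
        V.discount_spec_for_rate(2.2)


# ------------------------------------------------------------ Monte Carlo


def _tiny_config(**kw):
    return V.RunConfig(n_countries=6, n_segments=8, store_paths=False, **kw)


def test_monte_carlo_seed_reproducible():
    r1 = V.run_monte_carlo(2, config=_tiny_config(), seed=9)
    r2 = V.run_monte_carlo(2, config=_tiny_config(), seed=9)
    assert r1.draws.equals(r2.draws)
    assert r1.mean == r2.mean


def test_monte_carlo_mean_consistent_with_draws():
    r = V.run_monte_carlo(3, config=_tiny_config(), seed=1)
    assert r.mean == pytest.approx(r.draws["scc_total"].mean())


def test_partial_sccs_sum_to_total():
    r = V.run_monte_carlo(3, config=_tiny_config(), seed=2)
    parts = sum(
        r.draws[f"scc_{s}"] for s in ("energy", "mortality", "agriculture", "coastal")
    )
    np.testing.assert_allclose(
        parts, r.draws["scc_total"], rtol=1e-9, atol=1e-12
    )


def test_single_sector_partial_equals_total():
    r = V.run_monte_carlo(2, config=_tiny_config(sectors=("energy",)), seed=3)
    np.testing.assert_allclose(
        r.draws["scc_energy"], r.draws["scc_total"], rtol=1e-12
    )


def test_degenerate_ensemble_collapses_to_point():
    cfg = F.degenerate_run_config(n_countries=5, n_segments=5)
    r = V.run_monte_carlo(20, config=cfg, seed=4)
    vals = r.draws["scc_total"].to_numpy()
    np.testing.assert_allclose(vals, vals[0], rtol=1e-12)


def test_pulse_size_invariance():
    cfg_small = _tiny_config(pulse=PulseSpec(mass_mtc=0.05))
    cfg_big = _tiny_config(pulse=PulseSpec(mass_mtc=0.1))
    r_small = V.run_monte_carlo(2, config=cfg_small, seed=5)
    r_big = V.run_monte_carlo(2, config=cfg_big, seed=5)
    np.testing.assert_allclose(
        r_small.draws["scc_total"], r_big.draws["scc_total"], rtol=0.01
    )


def test_run_config_validation():
    with pytest.raises(ValueError, match="unknown sectors"):
        V.RunConfig(sectors=("energy", "widgets")).validate()
    with pytest.raises(ValueError, match="not packaged"):
        V.RunConfig(near_term_rate=4.0).validate()
    with pytest.raises(ValueError, match="draw"):
        V.RunConfig(n_draws=0).validate()
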