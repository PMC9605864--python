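"""Coastal adaptation: GEV return levels, exposure geometry, strategy
costs, least-cost optimality against independent recomputation."""

import numpy as np
import pytest
from scipy.stats import genextreme

from sccarbon import coastal as CO
from sccarbon import fixtures as F
from sccarbon import scenarios as S

YEARS = S.YEARS.copy()
N = YEARS.size
DF_FLAT = 0.98 ** np.arange(N)


def _segment(**overrides):
    base = dict(
        segment_id="s0",
        length_km=10.0,
        slope_m_per_km=2.0,
        pop_density=100.0,
        country_index=0,
        gev_loc=1.0,
        gev_scale=0.3,
        gev_shape=0.1,
        protect_cost=2e6,
        reloc_cost=2e4,
        slr_scaling=1.0,
    )
    base.update(overrides)
    return CO.CoastalSegment(**base)


# ------------------------------------------------------------------ GEV


def test_gumbel_return_level_closed_form():
    got = CO.gev_return_level(1.0, 0.5, 0.0, 100)
    assert got == pytest.approx(1.0 - 0.5 * np.log(-np.log(0.99)), abs=1e-12)
    assert got == pytest.approx(3.30, abs=0.005)


def test_return_period_of_one_rejected():
    with pytest.raises(ValueError, match="return period"):
        CO.gev_return_level(1.0, 0.5, 0.0, 1)


def test_return_level_increasing_in_period():
    for shape in (-0.2, 0.0, 0.2):
        levels = [CO.gev_return_level(1.0, 0.5, shape, rp) for rp in (10, 100, 1000)]
        assert np.all(np.diff(levels) > 0)


def test_return_level_matches_scipy():
    for shape in (-0.2, 0.15):
        ours = CO.gev_return_level(1.2, 0.4, shape, 250)
        ref = genextreme(c=-shape, loc=1.2, scale=0.4).ppf(1 - 1 / 250)
        assert ours == pytest.approx(ref, rel=1e-12)


def test_gev_mean_matches_scipy():
    for shape in (-0.2, 0.0, 0.15):
        ours = CO.gev_mean(1.2, 0.4, shape)
        ref = genextreme(c=-shape, loc=1.2, scale=0.4).mean()
        assert ours == pytest.approx(ref, rel=1e-10)


def test_mean_excess_monotone_and_tail_consistent():
    cs = np.linspace(-2, 6, 200)
    for shape in (-0.1, 0.0, 0.2):
        me = CO.gev_mean_excess(cs, 1.0, 0.3, shape)
        assert np.all(np.diff(me) <= 1e-12)
        assert np.all(me >= 0)
        # far below the support it equals E[X] - c exactly
        assert me[0] == pytest.approx(CO.gev_mean(1.0, 0.3, shape) - cs[0], rel=1e-9)
    # numerical-quadrature cross-check in the tail region
    dist = genextreme(c=-0.2, loc=1.0, scale=0.3)
    c = 2.0
    xs = np.linspace(c, c + 50, 400_000)
    ref = np.trapezoid(dist.sf(xs), xs)
    # closed-form tail approximation: a few percent is expected accuracy
    assert CO.gev_mean_excess(c, 1.0, 0.3, 0.2) == pytest.approx(ref, rel=0.05)


# -------------------------------------------------------------- exposure


def test_exposure_zero_height():
    e = CO.exposure(_segment(), 0.0, gdppc=1e4)
    assert e["population"] == 0.0 and e["value_usd"] == 0.0


def test_exposure_linear_in_height():
    seg = _segment()
    e1 = CO.exposure(seg, 1.0, gdppc=1e4)
    e2 = CO.exposure(seg, 2.0, gdppc=1e4)
    assert e2["area_km2"] == pytest.approx(2 * e1["area_km2"])
    assert e2["population"] == pytest.approx(2 * e1["population"])


def test_exposure_matches_integration_oracle():
    """Area below h equals the integral of inland width over elevation."""
    seg = _segment(length_km=7.0, slope_m_per_km=3.0)
    h = 1.8
    zs = np.linspace(0, h, 100_000)
    width_km = seg.length_km / seg.slope_m_per_km  # km of coast area per m
    area_ref = np.trapezoid(np.full_like(zs, width_km), zs)
    got = CO.exposure(seg, h, gdppc=1e4)["area_km2"]
    assert got == pytest.approx(area_ref, rel=1e-8)


# --------------------------------------------------------- strategy costs


def test_quiet_world_costs():
    """No sea-level rise, deterministic surge far below land: everything is
    free except building a (minimum-height) wall."""
    seg = _segment(gev_loc=-50.0, gev_scale=0.0, gev_shape=0.0)
    slr = np.zeros(N)
    cap = np.full(N, 1e4)
    for strat in ("noAdapt", "retreat10", "retreat1000"):
        assert CO.strategy_costs(seg, slr, YEARS, strat, DF_FLAT, cap) == 0.0
    assert CO.strategy_costs(seg, slr, YEARS, "protect100", DF_FLAT, cap) > 0.0
    plan = CO.least_cost_adaptation(seg, slr, YEARS, DF_FLAT, cap)
    assert all(s == "noAdapt" for s in plan.strategies)


def test_unknown_strategy_rejected():
    with pytest.raises(ValueError, match="unknown strategy"):
        CO.strategy_costs(
            _segment(), np.zeros(N), YEARS, "floatAway", DF_FLAT, np.full(N, 1e4)
        )


def test_noadapt_cost_monotone_in_slr():
    seg = _segment()
    cap = np.full(N, 1e4)
    slr = np.linspace(0, 0.8, N)
    ramp = np.linspace(0, 0.5, N)  # uniformly-higher alternative path
    c_base = CO.strategy_costs(seg, slr, YEARS, "noAdapt", DF_FLAT, cap)
    c_high = CO.strategy_costs(seg, slr + ramp, YEARS, "noAdapt", DF_FLAT, cap)
    assert c_high >= c_base


def test_protect_construction_increases_with_return_period():
    seg = _segment()
    cp = CO.CoastalCostParams(
        storm_damage_fraction=0.0, maintenance_fraction=0.0, abandon_fraction=0.0
    )
    cap = np.full(N, 1e4)
    slr = np.linspace(0, 0.5, N)
    costs = [
        CO.strategy_costs(seg, slr, YEARS, f"protect{rp}", DF_FLAT, cap, cp)
        for rp in (10, 100, 1000)
    ]
    assert costs[0] <= costs[1] <= costs[2]


def _naive_noadapt_npv(seg, slr, years, df, cap, cp):
    """Independent scalar recomputation of the no-adaptation NPV."""
    S_rel = slr - slr[0]
    pop_per_m = seg.length_km * seg.pop_density / seg.slope_m_per_km
    total = 0.0
    for i, _year in enumerate(years):
        vpm = pop_per_m * cp.capital_multiple * cap[i]
        storm = cp.storm_damage_fraction * vpm * CO.gev_mean_excess(
            max(0.0 - S_rel[i], 0.0),  # flood threshold above the sea
            seg.gev_loc, seg.gev_scale, seg.gev_shape,
        )
        prev = S_rel[i - 1] if i > 0 else 0.0
        inund = vpm * max(S_rel[i] - max(prev, 0.0), 0.0)
        total += df[i] / df[0] * (storm + inund)
    return total


def test_noadapt_npv_matches_independent_recomputation():
    seg = _segment()
    slr = np.linspace(0.1, 0.9, N)
    cap = np.linspace(1e4, 3e4, N)
    cp = CO.CoastalCostParams()
    ours = CO.strategy_costs(seg, slr, YEARS, "noAdapt", DF_FLAT, cap, cp)
    ref = _naive_noadapt_npv(seg, slr, YEARS, DF_FLAT, cap, cp)
    assert ours == pytest.approx(ref, rel=1e-10)


def test_least_cost_beats_all_alternatives_on_random_segments():
    """Exhaustive check: the chosen strategy's NPV is minimal in every
    planning period for 50 random segments, and ties prefer earlier
    strategies in (noAdapt, retreat, protect) order."""
    segments = F.make_segments(50, 5, seed=4)
    rng = np.random.default_rng(0)
    slr_global = np.linspace(0, 1.2, N) + 0.002 * rng.standard_normal(N).cumsum()
    cap = np.full(N, 2e4)
    for seg in segments:
        local = seg.slr_scaling * slr_global
        plan = CO.least_cost_adaptation(seg, local, YEARS, DF_FLAT, cap)
        for p, name in enumerate(plan.strategies):
            k = CO.STRATEGIES.index(name)
            npvs = plan.all_npv_costs[p]
            assert npvs[k] <= npvs.min() + 1e-9 * max(1.0, abs(npvs.min()))
            # tie-break: nothing cheaper-or-equal earlier in the ordering
            assert not np.any(npvs[:k] <= npvs[k])


def test_plan_deterministic_and_partition_identity(small_config):
    from sccarbon import sealevel as SL
    from sccarbon import valuation as V

    segments = F.make_segments(30, small_config.n_countries, seed=2)
    draw = S.sample_scenario(small_config, 5)
    years_sl = np.arange(1850, 2301)
    path = SL.run_sealevel(
        np.linspace(0, 2.5, years_sl.size), years_sl, SL.SeaLevelParams()
    )
    df = V.sdf_path(draw.world_gdppc(), V.discount_spec_for_rate(2.0), draw.years)
    out1 = CO.coastal_sector_damages(segments, path, draw, df)
    out2 = CO.coastal_sector_damages(segments, path, draw, df)
    np.testing.assert_array_equal(out1.damages, out2.damages)

    _, annual = CO.plan_segments(
        segments,
        np.array([s.slr_scaling for s in segments])[:, None]
        * path.slice_years(2020, 2300)[None, :],
        draw.years,
        df,
        draw.gdppc[[s.country_index for s in segments], :],
    )
    assert out1.damages.sum() == pytest.approx(annual.sum(), rel=1e-12)


def test_segment_frame_roundtrip(tmp_path):
    segments = F.make_segments(8, 3, seed=1)
    f = tmp_path / "segments.csv"
    CO.segments_to_frame(segments).to_csv(f, index=False)
    import pandas as pd

    loaded = CO.segments_from_frame(pd.read_csv(f))
    assert len(loaded) == 8
    assert loaded[0].segment_id == segments[0].segment_id
    assert loaded[3].length_km == pytest.approx(segments[3].length_km)
    with pytest.raises(ValueError, match="missing columns"):
        CO.segments_from_frame(pd.DataFrame({"segment_id": ["x"]}))


def test_segment_validation():
    with pytest.raises(ValueError, match="slope"):
        _segment(slope_m_per_km=0.0).validate()
    with pytest.raises(ValueError, match=">= 0"):
        _segment(length_km=-1.0).validate()
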