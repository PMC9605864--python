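"""Deterministic least-cost coastal adaptation.

Each coastal segment has a linear elevation profile, a population density,
a generalized extreme value (GEV) storm-surge climatology, and unit costs
for protection and relocation.  In each 50-year planning period the model
prices seven candidate strategies -- no adaptation, retreat to the local
sea level plus the 10/100/1000-yr surge return level, or protection to the
same heights -- and keeps the cheapest by net present value (ties broken
toward no adaptation, then retreat).  All coastal uncertainty enters
through the local sea-level path: given a path and segments the model is
deterministic.

Expected storm losses use the GEV mean-excess closed form
E[(X-c)+] ~ S(c) * (sigma + xi*(c-mu)) / (1 - xi), a generalized-Pareto
tail approximation that is exact in the upper tail and floored at the
no-threshold mean excess E[X] - c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

EULER_GAMMA = 0.5772156649015329

RETURN_PERIODS = (10, 100, 1000)
STRATEGIES = (
    "noAdapt",
    "retreat10", "retreat100", "retreat1000",
    "protect10", "protect100", "protect1000",
)


@dataclass
class CoastalSegment:
    segment_id: str
    length_km: float
    slope_m_per_km: float  # elevation gain per km inland (linear profile)
    pop_density: float  # persons per km^2
    country_index: int
    gev_loc: float  # m
    gev_scale: float  # m, >= 0 (0 = deterministic surge at loc)
    gev_shape: float  # xi, GEV convention (xi > 0: heavy tail)
    protect_cost: float  # USD per km per m of wall height
    reloc_cost: float  # USD per person relocated
    slr_scaling: float = 1.0

    def validate(self) -> None:
        if min(self.length_km, self.pop_density, self.protect_cost,
               self.reloc_cost) < 0:
            raise ValueError("segment lengths, densities and costs must be >= 0")
        if self.gev_scale < 0:
            raise ValueError("GEV scale must be >= 0")
        if self.slope_m_per_km <= 0:
            raise ValueError("elevation slope must be positive")


SEGMENT_FIELDS = (
    "segment_id", "length_km", "slope_m_per_km", "pop_density", "country_index",
    "gev_loc", "gev_scale", "gev_shape", "protect_cost", "reloc_cost",
    "slr_scaling",
)


def segments_to_frame(segments) -> pd.DataFrame:
    return pd.DataFrame(
        [{f: getattr(s, f) for f in SEGMENT_FIELDS} for s in segments]
    )


def segments_from_frame(df: pd.DataFrame) -> list:
    missing = set(SEGMENT_FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        seg = CoastalSegment(**{f: row[f] for f in SEGMENT_FIELDS})
        seg.segment_id = str(seg.segment_id)
        seg.country_index = int(seg.country_index)
        seg.validate()
        out.append(seg)
    return out


@dataclass
class CoastalCostParams:
    capital_multiple: float = 3.0  # capital per person, multiple of gdppc
    storm_damage_fraction: float = 0.25  # share of flooded value lost per event
    abandon_fraction: float = 0.25  # share of value written off on retreat
    maintenance_fraction: float = 0.01  # of cumulative construction, per yr
    min_wall_height: float = 0.5  # m; any wall has at least this height
    planning_period: int = 50  # yr


@dataclass
class AdaptationPlan:
    """Chosen strategy and realized cost components per planning period."""

    segment_id: str
    periods: list  # (start_year, end_year)
    strategies: list  # names from STRATEGIES
    npv_costs: np.ndarray  # (n_periods,), chosen strategy
    all_npv_costs: np.ndarray  # (n_periods, n_strategies)
    annual_costs: np.ndarray  # (n_years,) USD/yr, upfronts annualized


# ---------------------------------------------------------------------------
# GEV helpers (vectorized over segments)


def gev_return_level(loc, scale, shape, return_period):
    """Surge height exceeded once per ``return_period`` years on average
    (GEV quantile at 1 - 1/RP; Gumbel closed form at shape=0)."""
    rp = float(return_period)
    if rp <= 1.0:
        raise ValueError("return period must exceed 1 year")
    loc, scale, shape = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (loc, scale, shape))
    )
    y = -np.log(1.0 - 1.0 / rp)
    with np.errstate(divide="ignore", invalid="ignore"):
        gumbel = loc - scale * np.log(y)
        general = loc + scale / np.where(shape == 0.0, 1.0, shape) * (
            y ** -shape - 1.0
        )
    out = np.where(shape == 0.0, gumbel, general)
    out = np.where(scale == 0.0, loc, out)
    return out if out.shape else float(out)


def gev_mean(loc, scale, shape):
    loc, scale, shape = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (loc, scale, shape))
    )
    if (shape >= 1.0).any():
        raise ValueError("GEV mean undefined for shape >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        general = loc + scale * (gamma_fn(1.0 - shape) - 1.0) / np.where(
            shape == 0.0, 1.0, shape
        )
    out = np.where(shape == 0.0, loc + EULER_GAMMA * scale, general)
    out = np.where(scale == 0.0, loc, out)
    return out if out.shape else float(out)


def gev_survival(c, loc, scale, shape):
    """P(X > c), supporting scale == 0 (point mass at loc)."""
    c, loc, scale, shape = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (c, loc, scale, shape))
    )
    safe_scale = np.where(scale == 0.0, 1.0, scale)
    z = (c - loc) / safe_scale
    t = 1.0 + shape * z
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        core = np.where(
            shape == 0.0,
            np.exp(-z),
            np.where(t > 0.0, t ** np.where(shape == 0.0, 1.0, -1.0 / shape), np.inf),
        )
        # t <= 0 with shape > 0 means below support (F=0); shape < 0 above support
        core = np.where((t <= 0.0) & (shape > 0.0), np.inf, core)
        core = np.where((t <= 0.0) & (shape < 0.0), 0.0, core)
        surv = 1.0 - np.exp(-core)
    surv = np.where(scale == 0.0, (c < loc).astype(float), surv)
    return surv


def gev_mean_excess(c, loc, scale, shape):
    """E[(X - c)+]: GPD tail closed form floored at E[X] - c; exact for c
    below the support and in the upper tail, monotone nonincreasing in c."""
    c, loc, scale, shape = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (c, loc, scale, shape))
    )
    mean = gev_mean(loc, scale, shape)
    surv = gev_survival(c, loc, scale, shape)
    tail = surv * (scale + shape * np.maximum(c - loc, 0.0)) / (1.0 - shape)
    tail = np.where(scale == 0.0, np.maximum(loc - c, 0.0) * (c < loc), tail)
    return np.maximum(np.maximum(tail, mean - c), 0.0)


# ---------------------------------------------------------------------------
# exposure


def exposure(segment: CoastalSegment, height_m: float, gdppc: float,
             cost_params: CoastalCostParams | None = None) -> dict:
    """Population and capital value below ``height_m`` under the linear
    elevation profile: area = length * height / slope."""
    cost_params = cost_params or CoastalCostParams()
    h = max(float(height_m), 0.0)
    area_km2 = segment.length_km * h / segment.slope_m_per_km
    population = area_km2 * segment.pop_density
    value = population * cost_params.capital_multiple * gdppc
    return {"area_km2": area_km2, "population": population, "value_usd": value}


# ---------------------------------------------------------------------------
# vectorized planning engine


class _SegmentArrays:
    """Column store of segments for vectorized cost evaluation."""

    def __init__(self, segments):
        for f in SEGMENT_FIELDS:
            if f == "segment_id":
                self.segment_id = [s.segment_id for s in segments]
            elif f == "country_index":
                self.country_index = np.array(
                    [s.country_index for s in segments], dtype=int
                )
            else:
                setattr(
                    self, f, np.array([getattr(s, f) for s in segments], dtype=float)
                )
        self.n = len(segments)
        # persons (and value) per metre of elevation band
        self.pop_per_m = self.length_km * self.pop_density / self.slope_m_per_km
        self.surge_mean = gev_mean(self.gev_loc, self.gev_scale, self.gev_shape)
        self.return_levels = {
            rp: gev_return_level(self.gev_loc, self.gev_scale, self.gev_shape, rp)
            for rp in RETURN_PERIODS
        }


def _period_bounds(n_years: int, planning_period: int):
    bounds = []
    start = 0
    while start < n_years:
        bounds.append((start, min(start + planning_period, n_years)))
        start += planning_period
    return bounds


def _mean_excess_fast(arr: _SegmentArrays, c: np.ndarray) -> np.ndarray:
    """E[(X - c)+] for each segment's GEV, with the per-segment mean and
    parameter columns precomputed; same formula as :func:`gev_mean_excess`."""
    loc = arr.gev_loc[:, None]
    scale = arr.gev_scale[:, None]
    shape = arr.gev_shape[:, None]
    surv = gev_survival(c, loc, scale, shape)
    tail = surv * (scale + shape * np.maximum(c - loc, 0.0)) / (1.0 - shape)
    tail = np.where(scale == 0.0, np.maximum(loc - c, 0.0) * (c < loc), tail)
    return np.maximum(np.maximum(tail, arr.surge_mean[:, None] - c), 0.0)


def _annual_losses(arr: _SegmentArrays, S, S_prev, vpm, retreat_h, wall_h, cp):
    """Annual storm + inundation losses (n_seg, ny) given protection state."""
    r = retreat_h[:, None]
    w = wall_h[:, None]
    protected = w > S
    # storms damage the flood band above whatever is protected or abandoned
    thresh = np.where(protected, w - S, np.maximum(r - S, 0.0))
    storm = cp.storm_damage_fraction * vpm * _mean_excess_fast(arr, thresh)
    inund = vpm * np.maximum(S - np.maximum(S_prev, r), 0.0)
    inund = np.where(protected, 0.0, inund)
    return storm + inund


def _period_costs(arr: _SegmentArrays, S, S_prev, vpm, df, retreat_h, wall_h, cp):
    """NPV (n_strategies, n_seg), annualized cost paths
    (n_strategies, n_seg, ny) and post-period states for one period."""
    ny = S.shape[1]
    S_end = S[:, -1]
    n_strat = len(STRATEGIES)
    npv = np.empty((n_strat, arr.n))
    annual = np.empty((n_strat, arr.n, ny))
    new_r = np.empty((n_strat, arr.n))
    new_w = np.empty((n_strat, arr.n))

    # no adaptation
    losses = _annual_losses(arr, S, S_prev, vpm, retreat_h, wall_h, cp)
    npv[0] = losses @ df
    annual[0] = losses
    new_r[0], new_w[0] = retreat_h, wall_h

    for k, rp in enumerate(RETURN_PERIODS):
        q = arr.return_levels[rp]
        # retreat to S_end + surge(RP)
        r2 = np.maximum(retreat_h, S_end + q)
        relocated = np.maximum(r2 - np.maximum(retreat_h, S_prev[:, 0]), 0.0)
        upfront = (
            arr.reloc_cost * arr.pop_per_m * relocated
            + cp.abandon_fraction * vpm[:, 0] * relocated
        )
        losses = _annual_losses(arr, S, S_prev, vpm, r2, wall_h, cp)
        npv[1 + k] = losses @ df + upfront * df[0]
        annual[1 + k] = losses + (upfront / ny)[:, None]
        new_r[1 + k], new_w[1 + k] = r2, wall_h

        # protect to S_end + surge(RP)
        w2 = np.maximum.reduce(
            [wall_h, S_end + q, np.full(arr.n, cp.min_wall_height)]
        )
        build = arr.protect_cost * arr.length_km * np.maximum(w2 - wall_h, 0.0)
        maint = cp.maintenance_fraction * arr.protect_cost * arr.length_km * w2
        losses = _annual_losses(arr, S, S_prev, vpm, retreat_h, w2, cp)
        losses = losses + maint[:, None]
        npv[4 + k] = losses @ df + build * df[0]
        annual[4 + k] = losses + (build / ny)[:, None]
        new_r[4 + k], new_w[4 + k] = retreat_h, w2

    return npv, annual, new_r, new_w


def plan_segments(
    segments,
    local_slr: np.ndarray,
    years: np.ndarray,
    discount_factors: np.ndarray,
    capital_per_person: np.ndarray,
    cost_params: CoastalCostParams | None = None,
):
    """Greedy sequential least-cost planning for all segments.

    ``local_slr`` is (n_seg, n_years) local sea level relative to the first
    planning year; ``capital_per_person`` is (n_seg, n_years) USD.  Returns
    (plans, annual_costs (n_seg, n_years)).
    """
    cp = cost_params or CoastalCostParams()
    arr = segments if isinstance(segments, _SegmentArrays) else _SegmentArrays(segments)
    n_years = years.size
    S_all = local_slr - local_slr[:, 0:1]  # rise since planning start
    vpm_all = arr.pop_per_m[:, None] * cp.capital_multiple * capital_per_person

    retreat_h = np.zeros(arr.n)
    wall_h = np.zeros(arr.n)
    bounds = _period_bounds(n_years, cp.planning_period)
    annual_costs = np.zeros((arr.n, n_years))
    chosen = np.empty((len(bounds), arr.n), dtype=int)
    chosen_npv = np.empty((len(bounds), arr.n))
    all_npv = np.empty((len(bounds), len(STRATEGIES), arr.n))

    for p, (i0, i1) in enumerate(bounds):
        S = S_all[:, i0:i1]
        prev_col = S_all[:, i0 - 1 : i0] if i0 > 0 else np.zeros((arr.n, 1))
        S_prev = np.concatenate([prev_col, S[:, :-1]], axis=1)
        df = discount_factors[i0:i1] / discount_factors[i0]
        npv, annual, new_r, new_w = _period_costs(
            arr, S, S_prev, vpm_all[:, i0:i1], df, retreat_h, wall_h, cp
        )
        best = np.argmin(npv, axis=0)  # first minimum wins: noAdapt, then retreat
        idx = np.arange(arr.n)
        chosen[p] = best
        chosen_npv[p] = npv[best, idx]
        all_npv[p] = npv
        annual_costs[:, i0:i1] = annual[best, idx, :]
        retreat_h = new_r[best, idx]
        wall_h = new_w[best, idx]

    plans = [
        AdaptationPlan(
            segment_id=arr.segment_id[s],
            periods=[(int(years[i0]), int(years[i1 - 1])) for i0, i1 in bounds],
            strategies=[STRATEGIES[chosen[p, s]] for p in range(len(bounds))],
            npv_costs=chosen_npv[:, s].copy(),
            all_npv_costs=all_npv[:, :, s].copy(),
            annual_costs=annual_costs[s].copy(),
        )
        for s in range(arr.n)
    ]
    return plans, annual_costs


def strategy_costs(
    segment: CoastalSegment,
    local_slr: np.ndarray,
    years: np.ndarray,
    strategy: str,
    discount_factors: np.ndarray,
    capital_per_person: np.ndarray,
    cost_params: CoastalCostParams | None = None,
) -> float:
    """NPV cost of holding one strategy for every planning period."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {STRATEGIES}")
    cp = cost_params or CoastalCostParams()
    arr = _SegmentArrays([segment])
    S_all = local_slr[None, :] - local_slr[0]
    vpm = arr.pop_per_m[:, None] * cp.capital_multiple * capital_per_person[None, :]
    retreat_h = np.zeros(1)
    wall_h = np.zeros(1)
    total = 0.0
    k = STRATEGIES.index(strategy)
    for i0, i1 in _period_bounds(years.size, cp.planning_period):
        S = S_all[:, i0:i1]
        prev_col = S_all[:, i0 - 1 : i0] if i0 > 0 else np.zeros((1, 1))
        S_prev = np.concatenate([prev_col, S[:, :-1]], axis=1)
        df = discount_factors[i0:i1]
        npv, _, new_r, new_w = _period_costs(
            arr, S, S_prev, vpm[:, i0:i1], df / df[0], retreat_h, wall_h, cp
        )
        total += float(npv[k, 0]) * float(df[0] / discount_factors[0])
        retreat_h, wall_h = new_r[k], new_w[k]
    return total


def least_cost_adaptation(
    segment: CoastalSegment,
    local_slr: np.ndarray,
    years: np.ndarray,
    discount_factors: np.ndarray,
    capital_per_person: np.ndarray,
    cost_params: CoastalCostParams | None = None,
) -> AdaptationPlan:
    plans, _ = plan_segments(
        [segment], local_slr[None, :], years, discount_factors,
        capital_per_person[None, :], cost_params,
    )
    return plans[0]


def coastal_sector_damages(
    segments,
    sealevel_path,
    draw,
    discount_factors: np.ndarray,
    cost_params: CoastalCostParams | None = None,
):
    """Country-level coastal damages (USD/yr) for one draw.

    Deterministic given the sea-level path and segments; capital values come
    from the owning country's GDP per capita.
    """
    from .damages import SectorDamageSlice  # local import avoids a cycle

    cp = cost_params or CoastalCostParams()
    arr = segments if isinstance(segments, _SegmentArrays) else _SegmentArrays(segments)
    years = draw.years
    i0 = int(years[0]) - int(sealevel_path.years[0])
    gsl = sealevel_path.gsl[i0 : i0 + years.size]
    local = arr.slr_scaling[:, None] * gsl[None, :]
    capital_pp = draw.gdppc[arr.country_index, :]
    _, annual = plan_segments(arr, local, years, discount_factors, capital_pp, cp)

    n_countries = len(draw.countries)
    dollars = np.zeros((n_countries, years.size))
    np.add.at(dollars, arr.country_index, annual)
    return SectorDamageSlice("coastal", years, list(draw.countries), dollars)
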