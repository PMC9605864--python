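"""Reduced-complexity emissions-driven climate emulator.

Four-pool impulse-response carbon cycle whose pool timescales are scaled by
a state-dependent factor alpha chosen so the 100-yr integrated impulse
response (iIRF100) tracks background warming and cumulative sink uptake;
logarithmic CO2 forcing plus square-root CH4/N2O forcing and an exogenous
series; and a two-box thermal response.  This is the structure of the
published finite-amplitude impulse-response family of simple climate
models; every constant is configurable because the appropriate values are a
calibration product, not part of this package's contribution.

Units: emissions in GtC/yr internally (CO2 inputs in GtCO2/yr are converted
by 12/44), concentrations in ppm (CO2) / ppb (CH4, N2O), forcing in W m^-2,
temperature in K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .seeds import substream

GTC_PER_GTCO2 = 12.0 / 44.0
#: atmospheric CO2 burden per unit concentration
DEFAULT_GTC_PER_PPM = 2.124

HIST_YEAR_START = 1750
YEAR_END = 2300


@dataclass
class ClimateParams:
    """Carbon-cycle, forcing and thermal-response parameters."""

    a: np.ndarray = field(
        default_factory=lambda: np.array([0.2173, 0.2240, 0.2824, 0.2763])
    )
    tau: np.ndarray = field(
        default_factory=lambda: np.array([1.0e6, 394.4, 36.54, 4.304])
    )
    r0: float = 32.40  # yr
    rU: float = 0.019  # yr per GtC of cumulative uptake
    rT: float = 4.165  # yr per K
    C0: float = 278.0  # ppm
    F2x: float = 3.71  # W m^-2
    q: np.ndarray = field(default_factory=lambda: np.array([0.33, 0.41]))
    d: np.ndarray = field(default_factory=lambda: np.array([239.0, 4.1]))
    gtc_per_ppm: float = DEFAULT_GTC_PER_PPM
    alpha_bounds: tuple = (0.01, 100.0)

    ch4_lifetime: float = 9.3  # yr
    n2o_lifetime: float = 121.0  # yr
    ch4_0: float = 720.0  # ppb
    n2o_0: float = 270.0  # ppb
    ch4_forcing_coeff: float = 0.036  # W m^-2 per sqrt(ppb)
    n2o_forcing_coeff: float = 0.12  # W m^-2 per sqrt(ppb)
    mt_ch4_per_ppb: float = 2.84
    mt_n2o_per_ppb: float = 7.80

    def validate(self) -> None:
        if abs(float(np.sum(self.a)) - 1.0) > 1e-9:
            raise ValueError("carbon pool fractions must sum to 1")
        if (np.asarray(self.tau) <= 0).any() or (np.asarray(self.d) <= 0).any():
            raise ValueError("timescales must be positive")
        if (np.asarray(self.q) <= 0).any() or self.F2x <= 0:
            raise ValueError("q and F2x must be positive")

    def ecs(self) -> float:
        """Equilibrium warming for sustained CO2 doubling implied by params."""
        return float(self.F2x * np.sum(self.q))


@dataclass
class ClimateState:
    """Carbon pools (GtC), cumulative sink uptake (GtC), box temperatures."""

    R: np.ndarray = field(default_factory=lambda: np.zeros(4))
    U: float = 0.0
    T_boxes: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ch4_excess: float = 0.0  # ppb above pre-industrial
    n2o_excess: float = 0.0
    year: int = HIST_YEAR_START

    @property
    def T(self) -> float:
        return float(self.T_boxes.sum())

    def copy(self) -> "ClimateState":
        return ClimateState(
            self.R.copy(), self.U, self.T_boxes.copy(),
            self.ch4_excess, self.n2o_excess, self.year,
        )


@dataclass
class ClimatePath:
    """Annual CO2 concentration, total forcing and temperature anomaly
    (relative to the run's own 1850-1900 mean), 1750-2300."""

    years: np.ndarray
    co2_ppm: np.ndarray
    forcing: np.ndarray
    temperature: np.ndarray

    def at(self, year: int) -> dict:
        i = int(year) - int(self.years[0])
        return {
            "co2_ppm": self.co2_ppm[i],
            "forcing": self.forcing[i],
            "temperature": self.temperature[i],
        }

    def slice_years(self, start: int, end: int) -> np.ndarray:
        i0 = int(start) - int(self.years[0])
        return self.temperature[i0 : i0 + (end - start) + 1]


def iirf100(alpha: float, params: ClimateParams) -> float:
    """Integrated 100-yr impulse response at timescale scaling ``alpha``."""
    at = params.a * alpha * params.tau
    return float(np.sum(at * (1.0 - np.exp(-100.0 / (alpha * params.tau)))))


def solve_alpha(state: ClimateState, params: ClimateParams) -> float:
    """Scaling factor matching iIRF100 to r0 + rU*U + rT*T.

    iIRF100 is strictly increasing in alpha, so the bisection root is
    unique; targets outside the configured bracket are clamped with a
    warning.
    """
    target = params.r0 + params.rU * state.U + params.rT * state.T
    lo, hi = params.alpha_bounds
    f_lo = iirf100(lo, params) - target
    f_hi = iirf100(hi, params) - target
    if f_lo >= 0.0:
        warnings.warn(
            f"iIRF100 target {target:.3f} below solver bracket; alpha clamped to {lo}"
        )
        return lo
    if f_hi <= 0.0:
        warnings.warn(
            f"iIRF100 target {target:.3f} above solver bracket; alpha clamped to {hi}"
        )
        return hi
    return brentq(
        lambda alph: iirf100(alph, params) - target, lo, hi, xtol=1e-12, rtol=1e-14
    )


class _AlphaSolver:
    """Fast iIRF100 inverter for a fixed parameter set: log-grid seed plus
    Newton polish on the smooth monotone curve; agrees with
    :func:`solve_alpha` to well below its 1e-6 yr tolerance."""

    def __init__(self, params: ClimateParams, n_grid: int = 256):
        self.params = params
        lo, hi = params.alpha_bounds
        self.grid = np.geomspace(lo, hi, n_grid)
        at = params.a[None, :] * self.grid[:, None] * params.tau[None, :]
        self.iirf_grid = np.sum(
            at * (1.0 - np.exp(-100.0 / (self.grid[:, None] * params.tau[None, :]))),
            axis=1,
        )

    def solve(self, target: float) -> float:
        p = self.params
        lo, hi = p.alpha_bounds
        if target <= self.iirf_grid[0]:
            warnings.warn(
                f"iIRF100 target {target:.3f} below solver bracket; alpha clamped to {lo}"
            )
            return lo
        if target >= self.iirf_grid[-1]:
            warnings.warn(
                f"iIRF100 target {target:.3f} above solver bracket; alpha clamped to {hi}"
            )
            return hi
        alpha = float(np.interp(target, self.iirf_grid, self.grid))
        for _ in range(3):
            x = 100.0 / (alpha * p.tau)
            ex = np.exp(-x)
            f = float(np.sum(p.a * alpha * p.tau * (1.0 - ex))) - target
            fprime = float(np.sum(p.a * p.tau * (1.0 - ex - x * ex)))
            step = f / fprime
            alpha = min(max(alpha - step, lo), hi)
        return alpha


def step_carbon(
    state: ClimateState, emissions_gtc: float, alpha: float, params: ClimateParams
) -> float:
    """Advance the carbon pools one year; returns CO2 concentration (ppm).

    Exact exponential-decay discretization with constant within-year
    emissions; cumulative uptake U absorbs whatever emitted carbon does not
    remain airborne, so carbon is conserved to rounding.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    atau = alpha * params.tau
    decay = np.exp(-1.0 / atau)
    burden_before = float(state.R.sum())
    state.R = state.R * decay + params.a * emissions_gtc * atau * (1.0 - decay)
    burden_after = float(state.R.sum())
    state.U += emissions_gtc - (burden_after - burden_before)
    return params.C0 + burden_after / params.gtc_per_ppm


def step_trace_gas(excess_ppb: float, emissions_mt: float, lifetime: float,
                   mt_per_ppb: float) -> float:
    """One-box decay toward pre-industrial with exact-decay discretization."""
    decay = np.exp(-1.0 / lifetime)
    inflow = emissions_mt / mt_per_ppb
    return excess_ppb * decay + inflow * lifetime * (1.0 - decay)


def radiative_forcing(
    co2_ppm: float,
    ch4_ppb: float,
    n2o_ppb: float,
    params: ClimateParams,
    exogenous: float = 0.0,
) -> float:
    """Log CO2 + square-root CH4/N2O forcing plus an exogenous term."""
    if co2_ppm <= 0 or ch4_ppb <= 0 or n2o_ppb <= 0:
        raise ValueError("concentrations must be positive")
    f_co2 = params.F2x / np.log(2.0) * np.log(co2_ppm / params.C0)
    f_ch4 = params.ch4_forcing_coeff * (np.sqrt(ch4_ppb) - np.sqrt(params.ch4_0))
    f_n2o = params.n2o_forcing_coeff * (np.sqrt(n2o_ppb) - np.sqrt(params.n2o_0))
    return float(f_co2 + f_ch4 + f_n2o + exogenous)


def step_temperature(state: ClimateState, forcing: float, params: ClimateParams) -> float:
    """Advance the two thermal boxes one year; returns total temperature."""
    if not np.isfinite(forcing):
        raise ValueError("forcing must be finite")
    decay = np.exp(-1.0 / params.d)
    state.T_boxes = state.T_boxes * decay + params.q * forcing * (1.0 - decay)
    return state.T


# ---------------------------------------------------------------------------
# historical fixtures (synthetic, documented in docs/methods.md)


def historical_emissions(years: np.ndarray) -> dict:
    """Synthetic 1750-2019 global emission histories.

    Smooth exponential fossil-CO2 growth plus a land-use wedge, scaled so
    the spun-up 2020 state lands near the observed ~412 ppm and ~1.2 K;
    CH4/N2O ramps reproduce present-day concentrations approximately.
    Returns GtCO2/yr and Mt/yr series.
    """
    years = np.asarray(years, dtype=float)
    t = years - 1750.0
    fossil = 36.5 * np.exp(-(2019.0 - years) / 50.0)
    land_use = 3.0 * np.exp(-(((years - 1960.0) / 100.0) ** 2))
    co2 = fossil + land_use
    ch4 = 370.0 * (t / 269.0) ** 2.2
    n2o = 11.0 * (t / 269.0) ** 1.6
    return {"co2": co2, "ch4": ch4, "n2o": n2o}


def exogenous_forcing(years: np.ndarray) -> np.ndarray:
    """Packaged middle-of-the-road non-CO2/CH4/N2O forcing series (W m^-2):
    aerosols offset minor greenhouse gases historically, then clean up."""
    nodes_y = [1750.0, 1900.0, 1980.0, 2020.0, 2100.0, 2300.0]
    nodes_f = [0.0, -0.02, -0.20, -0.25, 0.12, 0.12]
    return np.interp(np.asarray(years, dtype=float), nodes_y, nodes_f)


@dataclass(frozen=True)
class PulseSpec:
    """A marginal CO2 emissions pulse.

    ``mass_mtc`` is in megatonnes of carbon; the per-tonne-CO2 divisor used
    for normalization is mass * 44/12 in tCO2 (applied once, in valuation).
    """

    year: int = 2020
    mass_mtc: float = 0.1

    @property
    def mass_gtc(self) -> float:
        return self.mass_mtc * 1e-3

    @property
    def mass_tco2(self) -> float:
        return self.mass_mtc * 1e6 * (44.0 / 12.0)

    def __post_init__(self):
        if self.mass_mtc <= 0:
            raise ValueError("pulse mass must be positive")


def run_climate(
    draw,
    params: ClimateParams,
    pulse: PulseSpec | None = None,
    hist: dict | None = None,
) -> ClimatePath:
    """Integrate 1750-2300: spin-up on the historical fixture, then the
    draw's emissions; with ``pulse``, emissions in the pulse year are
    incremented by the pulse mass and everything else is identical."""
    params.validate()
    years = np.arange(HIST_YEAR_START, YEAR_END + 1)
    n = years.size
    hist_years = np.arange(HIST_YEAR_START, 2020)
    if hist is None:
        hist = historical_emissions(hist_years)
    n_hist = hist_years.size

    co2_gtco2 = np.concatenate([hist["co2"], draw.co2])
    ch4_mt = np.concatenate([hist["ch4"], draw.ch4])
    n2o_mt = np.concatenate([hist["n2o"], draw.n2o])
    if pulse is not None:
        co2_gtco2 = co2_gtco2.copy()
        co2_gtco2[int(pulse.year) - HIST_YEAR_START] += pulse.mass_gtc / GTC_PER_GTCO2
    exog = exogenous_forcing(years)

    state = ClimateState()
    solver = _AlphaSolver(params)
    conc = np.empty(n)
    forcing = np.empty(n)
    temp_raw = np.empty(n)
    for i in range(n):
        alpha = solver.solve(params.r0 + params.rU * state.U + params.rT * state.T)
        conc[i] = step_carbon(state, co2_gtco2[i] * GTC_PER_GTCO2, alpha, params)
        state.ch4_excess = step_trace_gas(
            state.ch4_excess, ch4_mt[i], params.ch4_lifetime, params.mt_ch4_per_ppb
        )
        state.n2o_excess = step_trace_gas(
            state.n2o_excess, n2o_mt[i], params.n2o_lifetime, params.mt_n2o_per_ppb
        )
        forcing[i] = radiative_forcing(
            conc[i],
            params.ch4_0 + state.ch4_excess,
            params.n2o_0 + state.n2o_excess,
            params,
            exog[i],
        )
        temp_raw[i] = step_temperature(state, forcing[i], params)
        state.year = int(years[i])

    ref = temp_raw[(years >= 1850) & (years <= 1900)].mean()
    return ClimatePath(
        years=years, co2_ppm=conc, forcing=forcing, temperature=temp_raw - ref
    )


# ---------------------------------------------------------------------------
# parameter ensembles


ENSEMBLE_COLUMNS = (
    "a1", "a2", "a3", "a4", "tau2", "tau3", "tau4",
    "r0", "rU", "rT", "F2x", "q1", "q2", "d1", "d2",
)


def params_from_row(row: pd.Series) -> ClimateParams:
    a = np.array([row["a1"], row["a2"], row["a3"], row["a4"]], dtype=float)
    a = a / a.sum()
    return ClimateParams(
        a=a,
        tau=np.array([1.0e6, row["tau2"], row["tau3"], row["tau4"]], dtype=float),
        r0=float(row["r0"]),
        rU=float(row["rU"]),
        rT=float(row["rT"]),
        F2x=float(row["F2x"]),
        q=np.array([row["q1"], row["q2"]], dtype=float),
        d=np.array([row["d1"], row["d2"]], dtype=float),
    )


def sample_climate_params(
    source, seed: int, *, keys: tuple = ("climate",)
) -> ClimateParams:
    """Sample one parameter set.

    ``source`` is an ensemble table (DataFrame or CSV path, one row per
    member) sampled uniformly by row, or ``None`` for the package defaults.
    """
    if source is None:
        return ClimateParams()
    if not isinstance(source, pd.DataFrame):
        source = pd.read_csv(source)
    missing = set(ENSEMBLE_COLUMNS) - set(source.columns)
    if missing:
        raise ValueError(f"climate ensemble missing columns: {sorted(missing)}")
    rng = substream(seed, *keys)
    row = source.iloc[int(rng.integers(0, len(source)))]
    return params_from_row(row)
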