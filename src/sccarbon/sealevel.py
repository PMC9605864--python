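"""Component global sea-level model with Antarctic tipping and static
downscaling.

Each contributor carries one state variable: thermal expansion relaxes
toward an equilibrium proportional to warming; glaciers and the two ice
sheets melt at temperature-dependent rates bounded by their remaining
volumes; the Antarctic component adds a fast-disintegration rate while a
proxy temperature (a fixed multiple of the global anomaly) exceeds an
uncertain threshold; land-water storage follows a linear trend.  Local sea
level at a coastal segment is the global mean scaled by a time-invariant
factor.  All series are metres relative to 1900.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seeds import substream

YEAR0 = 1850  # integration start (spun up from the climate module's path)
REF_YEAR = 1900

COMPONENTS = ("thermal", "glaciers", "greenland", "antarctica", "landwater")


@dataclass
class SeaLevelParams:
    te_sensitivity: float = 0.35  # m per K at equilibrium
    te_timescale: float = 400.0  # yr
    glacier_volume: float = 0.5  # m SLE
    glacier_sensitivity: float = 0.0016  # m/yr/K
    glacier_t_eq: float = -0.1  # K
    glacier_exponent: float = 0.65
    greenland_volume: float = 7.36  # m SLE
    greenland_sensitivity: float = 0.0005  # m/yr/K
    antarctic_volume: float = 57.0  # m SLE
    antarctic_sensitivity: float = 0.0004  # m/yr/K
    antarctic_t_crit: float = 3.5  # K, in proxy-temperature units
    antarctic_proxy_scale: float = 1.2  # proxy T = scale * global anomaly
    fast_disintegration_rate: float = 0.002  # m/yr while threshold exceeded
    landwater_trend: float = 0.0003  # m/yr from 1900

    def validate(self) -> None:
        if min(self.glacier_volume, self.greenland_volume, self.antarctic_volume) < 0:
            raise ValueError("ice volumes must be non-negative")
        if self.te_timescale <= 0:
            raise ValueError("thermal-expansion timescale must be positive")
        if self.fast_disintegration_rate < 0:
            raise ValueError("fast-disintegration rate must be non-negative")


@dataclass
class SeaLevelState:
    te: float = 0.0
    glacier_volume: float = 0.0  # remaining, m SLE
    glacier_melted: float = 0.0
    greenland_melted: float = 0.0
    antarctic_melted: float = 0.0
    landwater: float = 0.0


@dataclass
class SeaLevelPath:
    """Annual component contributions and total GMSL (m rel. 1900), plus
    per-segment local series (scaling factor x global)."""

    years: np.ndarray
    components: dict  # name -> array
    gsl: np.ndarray
    local: np.ndarray | None = None  # (n_segments, n_years)
    tipped_year: int | None = None

    def slice_years(self, start: int, end: int, which: str = "gsl") -> np.ndarray:
        i0 = int(start) - int(self.years[0])
        arr = self.gsl if which == "gsl" else self.components[which]
        return arr[i0 : i0 + (end - start) + 1]


def step_thermal_expansion(state: SeaLevelState, T: float, p: SeaLevelParams) -> None:
    state.te += (p.te_sensitivity * T - state.te) / p.te_timescale


def step_glaciers(state: SeaLevelState, T: float, p: SeaLevelParams) -> None:
    if p.glacier_volume <= 0:
        return
    frac = max(state.glacier_volume / p.glacier_volume, 0.0)
    melt = p.glacier_sensitivity * (T - p.glacier_t_eq) * frac ** p.glacier_exponent
    melt = min(melt, state.glacier_volume)  # cannot melt more than remains
    melt = max(melt, -(p.glacier_volume - state.glacier_volume))  # nor regrow past V0
    state.glacier_volume -= melt
    state.glacier_melted += melt


def step_ice_sheets(state: SeaLevelState, T: float, p: SeaLevelParams) -> bool:
    """Advance both ice sheets one year; True if the Antarctic fast rate
    was active this year."""
    g_melt = max(0.0, p.greenland_sensitivity * T)
    g_melt = min(g_melt, p.greenland_volume - state.greenland_melted)
    state.greenland_melted += g_melt

    tripped = p.antarctic_proxy_scale * T > p.antarctic_t_crit
    a_rate = p.antarctic_sensitivity * T + (
        p.fast_disintegration_rate if tripped else 0.0
    )
    a_melt = min(a_rate, p.antarctic_volume - state.antarctic_melted)
    a_melt = max(a_melt, -state.antarctic_melted)  # melted-to-date stays >= 0
    state.antarctic_melted += a_melt
    return tripped


def run_sealevel(
    temperature: np.ndarray,
    years: np.ndarray,
    params: SeaLevelParams,
    segment_scalings: np.ndarray | None = None,
) -> SeaLevelPath:
    """Drive the component model with an annual global temperature anomaly
    path (must cover 1850 onward).  Components are referenced to 1900 so the
    total is exactly their sum."""
    params.validate()
    years = np.asarray(years)
    if years[0] > YEAR0:
        raise ValueError("temperature path must start at or before 1850")
    i0 = YEAR0 - int(years[0])
    yrs = years[i0:]
    temps = np.asarray(temperature, dtype=float)[i0:]

    state = SeaLevelState(glacier_volume=params.glacier_volume)
    n = yrs.size
    comps = {name: np.empty(n) for name in COMPONENTS}
    tipped_year = None
    for i in range(n):
        T = temps[i]
        step_thermal_expansion(state, T, params)
        step_glaciers(state, T, params)
        if step_ice_sheets(state, T, params) and tipped_year is None:
            tipped_year = int(yrs[i])
        state.landwater = params.landwater_trend * max(int(yrs[i]) - REF_YEAR, 0)
        comps["thermal"][i] = state.te
        comps["glaciers"][i] = state.glacier_melted
        comps["greenland"][i] = state.greenland_melted
        comps["antarctica"][i] = state.antarctic_melted
        comps["landwater"][i] = state.landwater

    iref = REF_YEAR - YEAR0
    for name in COMPONENTS:
        comps[name] = comps[name] - comps[name][iref]
    gsl = sum(comps[name] for name in COMPONENTS)

    local = None
    if segment_scalings is not None:
        local = np.asarray(segment_scalings, dtype=float)[:, None] * gsl[None, :]
    return SeaLevelPath(
        years=yrs, components=comps, gsl=gsl, local=local, tipped_year=tipped_year
    )


# ---------------------------------------------------------------------------
# parameter sampling

#: default prior sampler: name -> (kind, args) with kind in
#: {normal(mu, sd), lognormal(log-median, log-sd), uniform(lo, hi)}
DEFAULT_PRIORS = {
    "te_sensitivity": ("lognormal", (np.log(0.35), 0.25)),
    "te_timescale": ("uniform", (250.0, 550.0)),
    "glacier_sensitivity": ("lognormal", (np.log(0.0016), 0.3)),
    "glacier_t_eq": ("normal", (-0.1, 0.15)),
    "greenland_sensitivity": ("lognormal", (np.log(0.0005), 0.4)),
    "antarctic_sensitivity": ("lognormal", (np.log(0.0004), 0.5)),
    "antarctic_t_crit": ("normal", (3.5, 0.6)),
    "fast_disintegration_rate": ("uniform", (0.0, 0.006)),
    "landwater_trend": ("normal", (0.0003, 0.0001)),
}


def sample_sealevel_params(
    source, seed: int, *, keys: tuple = ("sealevel",)
) -> SeaLevelParams:
    """Sample parameters from a posterior-style table (DataFrame/CSV, one
    row per sample, sampled uniformly) or from the documented prior sampler
    (``source=None`` or a prior dict)."""
    rng = substream(seed, *keys)
    if source is not None and not isinstance(source, dict):
        if not isinstance(source, pd.DataFrame):
            source = pd.read_csv(source)
        row = source.iloc[int(rng.integers(0, len(source)))]
        return SeaLevelParams(**{k: float(v) for k, v in row.items()})
    priors = DEFAULT_PRIORS if source is None else source
    values = {}
    for name, (kind, args) in priors.items():
        if kind == "normal":
            values[name] = float(rng.normal(*args))
        elif kind == "lognormal":
            values[name] = float(np.exp(rng.normal(*args)))
        elif kind == "uniform":
            values[name] = float(rng.uniform(*args))
        else:
            raise ValueError(f"unknown prior kind {kind!r} for {name!r}")
    values["fast_disintegration_rate"] = max(
        values.get("fast_disintegration_rate", 0.0), 0.0
    )
    params = SeaLevelParams(**values)
    params.validate()
    return params
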