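"""Joint probabilistic socioeconomic--emissions scenario generator.

Emulates the statistical structure of multi-century probabilistic
projections of country-level population and GDP per capita together with
correlated global CO2/CH4/N2O emissions, 2020--2300.  The generator is
quantile-anchored: world population in 2300, the cumulative-average
per-capita growth rate, and net CO2 emissions in 2100 each follow a
two-piece (log)normal passing exactly through configured 5/50/95 anchors,
and the growth--emissions dependence is a Gaussian copula whose correlation
is the configured sensitivity coefficient.

A :class:`ScenarioDraw` holds, per country and year, population, GDP per
capita and the baseline all-cause mortality rate, plus global greenhouse-gas
emission paths.  Draws can be round-tripped through a long-format CSV
(``draw_id, variable, country, year, value``).
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import (
    check_anchors,
    split_lognormal_from_z,
    split_normal_from_z,
)
from .seeds import substream

YEAR_START = 2020
YEAR_END = 2300
YEARS = np.arange(YEAR_START, YEAR_END + 1)
N_YEARS = YEARS.size

VARIABLES = ("pop", "gdppc", "mortrate", "co2", "ch4", "n2o")
GLOBAL_VARIABLES = ("co2", "ch4", "n2o")
WORLD = "WLD"


def default_country_codes(n: int) -> list[str]:
    """Deterministic synthetic ISO-alpha-3-style codes: AAA, AAB, ..."""
    letters = string.ascii_uppercase
    codes = []
    for i in range(n):
        a, rem = divmod(i, 26 * 26)
        b, c = divmod(rem, 26)
        codes.append(letters[a] + letters[b] + letters[c])
    return codes


@dataclass(frozen=True)
class QuantileAnchor:
    """A (5%, 50%, 95%) quantile anchor triple for one scalar."""

    q05: float
    q50: float
    q95: float

    def validate(self, name: str) -> None:
        check_anchors(name, self.q05, self.q50, self.q95)


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibrated scenario-generator settings.

    Quantile anchors are for: world population in 2300 (persons), the
    2020-2300 cumulative-average world per-capita growth rate (fraction per
    year), and global net CO2 emissions in 2100 (GtCO2 per year, may be
    negative).  ``growth_emissions_sensitivity`` is the Gaussian-copula
    correlation linking realized growth and emissions (0 decouples them).
    """

    pop_2300: QuantileAnchor = QuantileAnchor(2.8e9, 7.3e9, 2.1e10)
    pop_2020: float = 7.84e9
    pop_peak_median: float = 11.0e9
    pop_peak_log_sd: float = 0.25
    pop_peak_year: float = 2130.0
    pop_peak_year_sd: float = 30.0

    growth: QuantileAnchor = QuantileAnchor(0.0017, 0.0088, 0.027)
    gdppc_2020: float = 11_000.0
    growth_profile_swing: float = 0.005  # early-minus-late tilt, fraction/yr
    growth_noise_sd: float = 0.002

    co2_2100: QuantileAnchor = QuantileAnchor(-7.0, 17.0, 62.0)
    co2_2020: float = 42.0
    co2_post2100_decline: float = 0.04  # GtCO2/yr per year after 2100
    co2_floor: float = -25.0
    growth_emissions_sensitivity: float = 0.5

    ch4_anchor_path: tuple = ((2020, 375.0), (2100, 230.0), (2300, 150.0))
    ch4_log_sd: float = 0.25
    n2o_anchor_path: tuple = ((2020, 10.5), (2100, 9.0), (2300, 7.0))
    n2o_log_sd: float = 0.15

    n_countries: int = 184
    country_income_log_sd: float = 1.0
    income_convergence_timescale: float = 150.0  # years
    share_dirichlet_concentration: float = 5_000.0

    # baseline mortality rate = mort_a + mort_b * gdppc ** (-mort_c), clipped
    mort_a: float = 0.0025
    mort_b: float = 0.0713
    mort_c: float = 0.3

    def validate(self) -> None:
        self.pop_2300.validate("population 2300")
        self.growth.validate("cumulative growth")
        self.co2_2100.validate("CO2 emissions 2100")
        if not (YEAR_START <= self.pop_peak_year <= YEAR_END):
            raise ValueError("population peak year must lie in [2020, 2300]")
        if self.n_countries < 1:
            raise ValueError("country count must be >= 1")


def calibrate_generator(anchors: dict) -> GeneratorConfig:
    """Build a validated :class:`GeneratorConfig` from a quantile-anchor set.

    ``anchors`` maps a subset of {"pop_2300", "growth", "co2_2100"} to
    (q05, q50, q95) triples; other fields may be passed through by keyword
    name.  Deterministic given anchors; unordered triples raise
    :class:`~sccarbon.distributions.AnchorOrderError` naming the anchor.
    """
    kwargs = {}
    for key in ("pop_2300", "growth", "co2_2100"):
        if key in anchors:
            tri = anchors[key]
            anchor = tri if isinstance(tri, QuantileAnchor) else QuantileAnchor(*tri)
            anchor.validate(key)
            kwargs[key] = anchor
    for key, val in anchors.items():
        if key not in ("pop_2300", "growth", "co2_2100"):
            if key not in {f.name for f in dataclasses.fields(GeneratorConfig)}:
                raise ValueError(f"unknown generator anchor/field {key!r}")
            kwargs[key] = val
    config = GeneratorConfig(**kwargs)
    config.validate()
    return config


@dataclass
class ScenarioDraw:
    """One joint realization of socioeconomics and emissions, 2020--2300."""

    years: np.ndarray
    countries: list[str]
    population: np.ndarray  # (n_countries, n_years), persons
    gdppc: np.ndarray  # (n_countries, n_years), constant USD
    mortality_rate: np.ndarray  # (n_countries, n_years), deaths/person/yr
    co2: np.ndarray  # (n_years,), GtCO2/yr, may be negative
    ch4: np.ndarray  # (n_years,), Mt/yr
    n2o: np.ndarray  # (n_years,), Mt/yr
    draw_id: int = 0
    seed: int = 0

    def validate(self) -> None:
        n_c, n_y = len(self.countries), self.years.size
        expected = (n_c, n_y)
        for name in ("population", "gdppc", "mortality_rate"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, want {expected}")
        if np.diff(self.years).min(initial=1) != 1 or self.years[0] != YEAR_START:
            raise ValueError("years must cover 2020-2300 with no gaps")
        if self.years[-1] != YEAR_END:
            raise ValueError("years must cover 2020-2300 with no gaps")
        if not (self.population > 0).all():
            raise ValueError("population must be positive")
        if not (self.gdppc > 0).all():
            raise ValueError("GDP per capita must be positive")
        if not ((self.mortality_rate > 0) & (self.mortality_rate < 1)).all():
            raise ValueError("baseline mortality rate must lie in (0, 1)")
        for name in GLOBAL_VARIABLES:
            if getattr(self, name).shape != (n_y,):
                raise ValueError(f"{name} must be an annual global series")

    # world aggregates -----------------------------------------------------
    def world_population(self) -> np.ndarray:
        return self.population.sum(axis=0)

    def world_gdppc(self) -> np.ndarray:
        """Population-weighted mean GDP per capita."""
        return (self.population * self.gdppc).sum(axis=0) / self.world_population()

    def world_gdp(self) -> np.ndarray:
        return (self.population * self.gdppc).sum(axis=0)

    def cumulative_average_growth(self) -> float:
        """Annualized geometric-average world per-capita growth 2020->2300."""
        g = self.world_gdppc()
        return float((g[-1] / g[0]) ** (1.0 / (N_YEARS - 1)) - 1.0)


def _anchor_path_multiplied(anchor_path, multiplier: float) -> np.ndarray:
    yrs = [p[0] for p in anchor_path]
    vals = [p[1] for p in anchor_path]
    return np.interp(YEARS, yrs, vals) * multiplier


def _world_population_path(config: GeneratorConfig, rng: np.random.Generator):
    z = rng.standard_normal()
    z_peak_year = rng.standard_normal()
    p2300 = float(
        split_lognormal_from_z(
            z, config.pop_2300.q05, config.pop_2300.q50, config.pop_2300.q95
        )
    )
    peak_raw = config.pop_peak_median * np.exp(config.pop_peak_log_sd * z)
    p2020 = config.pop_2020
    if p2300 >= peak_raw:
        # still-rising world: treat 2300 as the (censored) peak
        peak, t_peak = max(p2300, 1.0001 * p2020), float(YEAR_END)
    else:
        peak = max(peak_raw, 1.0001 * p2020)
        t_peak = float(
            np.clip(
                config.pop_peak_year + config.pop_peak_year_sd * z_peak_year,
                2040.0,
                2295.0,
            )
        )
    path = np.empty(N_YEARS)
    rise = YEARS <= t_peak
    frac = (YEARS[rise] - YEAR_START) / (t_peak - YEAR_START)
    path[rise] = p2020 + (peak - p2020) * np.sin(0.5 * np.pi * frac) ** 2
    if not rise.all():
        frac_d = (YEARS[~rise] - t_peak) / (YEAR_END - t_peak)
        path[~rise] = peak * (p2300 / peak) ** frac_d
    else:
        path[-1] = p2300  # t_peak == 2300 lands on the sampled level exactly
    return path


def _world_gdppc_path(config: GeneratorConfig, rng: np.random.Generator):
    """Returns (path, z_growth). Geometric-average growth equals the sampled
    split-normal rate exactly: log increments are the base log rate plus a
    zero-sum declining tilt and zero-sum noise."""
    z_g = rng.standard_normal()
    g = float(
        split_normal_from_z(
            z_g, config.growth.q05, config.growth.q50, config.growth.q95
        )
    )
    n_steps = N_YEARS - 1
    tilt = np.linspace(1.0, -1.0, n_steps) * config.growth_profile_swing
    noise = rng.normal(0.0, config.growth_noise_sd, size=n_steps)
    dev = (tilt - tilt.mean()) + (noise - noise.mean())
    log_inc = np.log1p(g) + dev
    log_path = np.concatenate([[0.0], np.cumsum(log_inc)])
    return config.gdppc_2020 * np.exp(log_path), z_g


def _co2_path(config: GeneratorConfig, rng: np.random.Generator, z_g: float):
    rho = float(np.clip(config.growth_emissions_sensitivity, -0.95, 0.95))
    z_e = rho * z_g + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
    e2100 = float(
        split_normal_from_z(
            z_e, config.co2_2100.q05, config.co2_2100.q50, config.co2_2100.q95
        )
    )
    path = np.empty(N_YEARS)
    to2100 = YEARS <= 2100
    frac = (YEARS[to2100] - YEAR_START) / (2100 - YEAR_START)
    path[to2100] = config.co2_2020 + (e2100 - config.co2_2020) * frac
    path[~to2100] = e2100 - config.co2_post2100_decline * (YEARS[~to2100] - 2100)
    return np.maximum(path, config.co2_floor), e2100


def _country_structure(config: GeneratorConfig, rng: np.random.Generator):
    """Base population shares, their slow Dirichlet evolution, and initial
    relative incomes."""
    n = config.n_countries
    base_weight = 1.0 / (np.arange(n) + 5.0)  # heavy-tailed size spectrum
    base_weight /= base_weight.sum()
    kappa = config.share_dirichlet_concentration
    decade_years = np.arange(YEAR_START, YEAR_END + 10, 10.0)
    shares = np.empty((decade_years.size, n))
    frozen = n == 1 or not np.isfinite(kappa)  # infinite concentration: static
    shares[0] = base_weight if frozen else rng.dirichlet(kappa * base_weight)
    for k in range(1, decade_years.size):
        if frozen:
            shares[k] = shares[0]
        else:
            sample = rng.dirichlet(kappa * np.maximum(shares[k - 1], 1e-6))
            sample = np.maximum(sample, 1e-9)  # tiny countries never vanish
            shares[k] = sample / sample.sum()
    # annual linear interpolation, renormalized so shares sum to 1 exactly
    annual = np.empty((n, N_YEARS))
    for i in range(n):
        annual[i] = np.interp(YEARS, decade_years, shares[:, i])
    annual /= annual.sum(axis=0, keepdims=True)
    rel_income = np.exp(rng.normal(0.0, config.country_income_log_sd, size=n))
    return annual, rel_income


def mortality_rate_schedule(config: GeneratorConfig, gdppc: np.ndarray):
    """Deterministic baseline all-cause mortality rate declining in income."""
    rate = config.mort_a + config.mort_b * np.asarray(gdppc, float) ** (-config.mort_c)
    return np.clip(rate, 1e-4, 0.5)


def sample_scenario(config: GeneratorConfig, seed: int) -> ScenarioDraw:
    """Draw one joint scenario.  Identical (config, seed) gives identical
    draws; all randomness flows through named substreams of ``seed``."""
    config.validate()
    pop_w = _world_population_path(config, substream(seed, "scenario", "pop"))
    gdppc_w, z_g = _world_gdppc_path(config, substream(seed, "scenario", "growth"))
    co2, _ = _co2_path(config, substream(seed, "scenario", "co2"), z_g)
    rng_gas = substream(seed, "scenario", "gases")
    ch4 = _anchor_path_multiplied(
        config.ch4_anchor_path, float(np.exp(config.ch4_log_sd * rng_gas.standard_normal()))
    )
    n2o = _anchor_path_multiplied(
        config.n2o_anchor_path, float(np.exp(config.n2o_log_sd * rng_gas.standard_normal()))
    )

    shares, rel_income = _country_structure(
        config, substream(seed, "scenario", "countries")
    )
    population = shares * pop_w[np.newaxis, :]

    # relative incomes converge toward the world level; renormalize so the
    # population-weighted mean reproduces the anchored world path exactly
    decay = np.exp(-(YEARS - YEAR_START) / config.income_convergence_timescale)
    log_rel = np.log(rel_income)[:, np.newaxis] * decay[np.newaxis, :]
    gdppc = np.exp(log_rel) * gdppc_w[np.newaxis, :]
    weighted_mean = (shares * gdppc).sum(axis=0)
    gdppc *= (gdppc_w / weighted_mean)[np.newaxis, :]

    draw = ScenarioDraw(
        years=YEARS.copy(),
        countries=default_country_codes(config.n_countries),
        population=population,
        gdppc=gdppc,
        mortality_rate=mortality_rate_schedule(config, gdppc),
        co2=co2,
        ch4=ch4,
        n2o=n2o,
        draw_id=int(seed),
        seed=int(seed),
    )
    draw.validate()
    return draw


def sample_scenarios(
    config: GeneratorConfig, n: int, master_seed: int
) -> list[ScenarioDraw]:
    """n independent draws with per-draw seeds derived from one master seed."""
    rng = substream(master_seed, "scenario", "drawseeds")
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [sample_scenario(config, int(s)) for s in seeds]


# ---------------------------------------------------------------------------
# quantiles


def _draw_series(draw: ScenarioDraw, variable: str, country: str) -> np.ndarray:
    if variable in GLOBAL_VARIABLES:
        return getattr(draw, variable)
    if variable == "pop":
        if country == WORLD:
            return draw.world_population()
        arr = draw.population
    elif variable == "gdppc":
        if country == WORLD:
            return draw.world_gdppc()
        arr = draw.gdppc
    elif variable == "mortrate":
        if country == WORLD:
            w = draw.population
            return (w * draw.mortality_rate).sum(axis=0) / w.sum(axis=0)
        arr = draw.mortality_rate
    else:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {VARIABLES}"
        )
    return arr[draw.countries.index(country)]


def scenario_quantiles(
    draws: Sequence[ScenarioDraw],
    variable: str,
    year: int,
    probs: Iterable[float],
    country: str = WORLD,
) -> np.ndarray:
    """Empirical cross-draw quantiles (numpy ``linear`` interpolation) of one
    variable at one year.  Monotone in ``probs`` by construction."""
    draws = list(draws)
    if len(draws) < 2:
        raise ValueError("need at least 2 draws for empirical quantiles")
    probs = np.asarray(list(probs), dtype=float)
    if ((probs <= 0) | (probs >= 1)).any():
        raise ValueError("probs must lie strictly in (0, 1)")
    iy = int(year) - YEAR_START
    if not 0 <= iy < N_YEARS:
        raise ValueError(f"year {year} outside 2020-2300")
    values = np.array([_draw_series(d, variable, country)[iy] for d in draws])
    return np.quantile(values, probs, method="linear")


# ---------------------------------------------------------------------------
# long-format CSV round trip (draw_id, variable, country, year, value)


def write_scenarios(draws: Sequence[ScenarioDraw], path) -> None:
    frames = []
    for d in draws:
        for name, arr in (
            ("pop", d.population),
            ("gdppc", d.gdppc),
            ("mortrate", d.mortality_rate),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "draw_id": d.draw_id,
                        "variable": name,
                        "country": np.repeat(d.countries, d.years.size),
                        "year": np.tile(d.years, len(d.countries)),
                        "value": arr.ravel(),
                    }
                )
            )
        for name in GLOBAL_VARIABLES:
            frames.append(
                pd.DataFrame(
                    {
                        "draw_id": d.draw_id,
                        "variable": name,
                        "country": WORLD,
                        "year": d.years,
                        "value": getattr(d, name),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_scenarios(path) -> list[ScenarioDraw]:
    """Read draws from the long-format CSV; hard errors on gaps or
    impossible values, naming the offending years."""
    df = pd.read_csv(path)
    required = {"draw_id", "variable", "country", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scenario file missing columns: {sorted(missing)}")
    draws = []
    for draw_id, g in df.groupby("draw_id", sort=True):
        countries = sorted(
            set(g.loc[~g["variable"].isin(GLOBAL_VARIABLES), "country"])
        )
        arrays = {}
        for name in ("pop", "gdppc", "mortrate"):
            sub = g[g["variable"] == name]
            pivot = sub.pivot_table(
                index="country", columns="year", values="value", aggfunc="first"
            ).reindex(index=countries, columns=YEARS)
            gaps = [int(y) for y in YEARS if pivot[y].isna().any()]
            if gaps:
                raise ValueError(
                    f"draw {draw_id}: variable {name!r} has missing years {gaps}"
                )
            arrays[name] = pivot.to_numpy(dtype=float)
        globals_ = {}
        for name in GLOBAL_VARIABLES:
            sub = g[g["variable"] == name].set_index("year")["value"]
            sub = sub.reindex(YEARS)
            gaps = [int(y) for y in YEARS[sub.isna().to_numpy()]]
            if gaps:
                raise ValueError(
                    f"draw {draw_id}: variable {name!r} has missing years {gaps}"
                )
            globals_[name] = sub.to_numpy(dtype=float)
        if (arrays["pop"] <= 0).any():
            raise ValueError(f"draw {draw_id}: non-positive population")
        draw = ScenarioDraw(
            years=YEARS.copy(),
            countries=countries,
            population=arrays["pop"],
            gdppc=arrays["gdppc"],
            mortality_rate=arrays["mortrate"],
            co2=globals_["co2"],
            ch4=globals_["ch4"],
            n2o=globals_["n2o"],
            draw_id=int(draw_id),
            seed=int(draw_id),
        )
        draw.validate()
        draws.append(draw)
    return draws
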