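"""Stochastic discounting, marginal damages and SC-CO2 aggregation.

The social cost of CO2 is the present value, per tonne of CO2, of the
difference in monetized damages between a baseline run and a run that is
identical except for a small CO2 pulse in 2020:

    SDF_t = (1 + rho)^-(t-2020) * (c_t / c_2020)^-eta
    MD_t  = sum_sectors sum_regions (damages with pulse - baseline) / pulse tCO2
    SC-CO2 = sum_{t=2020}^{2300} SDF_t * MD_t

c_t is world average per-capita consumption (GDP net of climate damages by
default), so the discount rate is stochastic: r_t = rho + eta * g_t with
g_t the realized average consumption growth since the pulse year.  Partial
SC-CO2 values per sector use the same SDF_t as the total, which makes them
add up to the total exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import climate as _climate
from . import coastal as _coastal
from . import damages as _damages
from . import scenarios as _scenarios
from . import sealevel as _sealevel
from .climate import PulseSpec
from .seeds import substream

SECTORS = _damages.SECTORS
BASE_YEAR = 2020
QUANTILE_PROBS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class DiscountSpec:
    """Ramsey discounting parameters: pure time preference rho (per yr) and
    consumption elasticity eta."""

    rho: float
    eta: float
    label: str = ""

    def __post_init__(self):
        if self.rho < 0 or self.eta < 0:
            raise ValueError("rho and eta must be non-negative")


#: (rho, eta) pairs calibrated to near-term risk-free rates of 1.5/2/2.5/3%.
PACKAGED_DISCOUNT_SPECS = {
    1.5: DiscountSpec(0.0001, 1.02, "1.5%"),
    2.0: DiscountSpec(0.002, 1.24, "2.0%"),
    2.5: DiscountSpec(0.005, 1.42, "2.5%"),
    3.0: DiscountSpec(0.008, 1.57, "3.0%"),
}


def discount_spec_for_rate(rate: float) -> DiscountSpec:
    if rate not in PACKAGED_DISCOUNT_SPECS:
        raise ValueError(
            f"near-term rate {rate} not packaged; valid: "
            f"{sorted(PACKAGED_DISCOUNT_SPECS)}"
        )
    return PACKAGED_DISCOUNT_SPECS[rate]


# ---------------------------------------------------------------------------
# deflation

#: US GDP implicit price deflator, 2020 = 1 (synthetic-but-plausible table;
#: replaceable by the official series).
DEFAULT_DEFLATOR = {
    1990: 0.607,
    2005: 0.810,
    2011: 0.879,
    2019: 0.988,
    2020: 1.000,
}


def to_2020_usd(value, base_year: int, table: dict | None = None):
    """Convert a value quoted in ``base_year`` dollars to 2020 dollars."""
    table = table or DEFAULT_DEFLATOR
    if base_year not in table:
        raise KeyError(f"no deflator entry for base year {base_year}")
    return np.asarray(value, dtype=float) * (table[2020] / table[base_year])


# ---------------------------------------------------------------------------
# paths


def consumption_path(
    draw, total_damages: np.ndarray, floor: float = 100.0
) -> tuple[np.ndarray, int]:
    """World per-capita consumption: (world GDP - damages) / population,
    floored at a small positive level.  Returns (c_t, floored-year count)."""
    pop = draw.world_population()
    c = (draw.world_gdp() - np.asarray(total_damages, float)) / pop
    floored = int((c < floor).sum())
    return np.maximum(c, floor), floored


def sdf_path(c: np.ndarray, spec: DiscountSpec, years: np.ndarray) -> np.ndarray:
    """Stochastic discount factors; SDF at the base year is exactly 1."""
    t = np.asarray(years) - BASE_YEAR
    return (1.0 + spec.rho) ** (-t) * (c / c[0]) ** (-spec.eta)


def marginal_damage_path(
    baseline: dict, pulsed: dict, pulse: PulseSpec
) -> dict[str, np.ndarray]:
    """Per-sector marginal damages, USD per tonne CO2 per year:
    (with-pulse - baseline) summed over the sector's regions, divided by the
    pulse mass in tCO2 (the 44/12 conversion is applied here, once)."""
    if set(baseline) != set(pulsed):
        raise ValueError("baseline and pulsed runs cover different sectors")
    divisor = pulse.mass_tco2
    return {
        sector: (pulsed[sector].total() - baseline[sector].total()) / divisor
        for sector in baseline
    }


def scc_from_draw(md: np.ndarray, sdf: np.ndarray) -> float:
    """Present value: inner product of marginal damages and SDFs, 2020-2300."""
    return float(np.dot(np.asarray(md, float), np.asarray(sdf, float)))


def partial_scc(sector: str, md_by_sector: dict, sdf: np.ndarray) -> float:
    """Sector SC-CO2 with the total run's discount path (so partials sum to
    the total exactly)."""
    return scc_from_draw(md_by_sector[sector], sdf)


def near_term_rate(spec: DiscountSpec, consumption_paths, years: np.ndarray) -> float:
    """Mean risk-free rate r_t = rho + eta * g_t over the first decade
    (t = 2021..2030), averaged across draws; in percent.  g_t is the
    annualized consumption growth from the pulse year to t."""
    horizon = (years >= BASE_YEAR + 1) & (years <= BASE_YEAR + 10)
    t = (np.asarray(years) - BASE_YEAR)[horizon]
    rates = []
    for c in np.atleast_2d(np.asarray(consumption_paths, dtype=float)):
        g = (c[horizon] / c[0]) ** (1.0 / t) - 1.0
        rates.append(np.mean(spec.rho + spec.eta * g))
    return float(np.mean(rates)) * 100.0


# ---------------------------------------------------------------------------
# Monte Carlo orchestration


@dataclass
class RunConfig:
    """Study-level settings for a Monte Carlo SC-CO2 run."""

    mode: str = "synthetic"  # or "data"
    n_draws: int = 100
    master_seed: int = 0
    near_term_rate: float = 2.0
    sectors: tuple = SECTORS
    pulse: PulseSpec = field(default_factory=PulseSpec)
    n_countries: int = 184
    n_segments: int = 500
    n_climate_ensemble: int = 100
    scenario_config: _scenarios.GeneratorConfig | None = None
    scenario_draws: object = None  # data mode: pre-loaded draws, sampled by row
    climate_source: object = None  # DataFrame/path; None -> fixture ensemble
    sealevel_source: object = None  # DataFrame/path/prior dict; None -> priors
    segments: object = None  # list of CoastalSegment; None -> synthetic
    damage_params: _damages.DamageParams = field(
        default_factory=_damages.DamageParams
    )
    cost_params: _coastal.CoastalCostParams = field(
        default_factory=_coastal.CoastalCostParams
    )
    consumption_basis: str = "net"  # or "gross"
    consumption_floor: float = 100.0
    ag_theta_fixed: float | None = None
    store_paths: bool = True

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        discount_spec_for_rate(self.near_term_rate)
        unknown = set(self.sectors) - set(SECTORS)
        if unknown:
            raise ValueError(f"unknown sectors: {sorted(unknown)}")
        if self.consumption_basis not in ("net", "gross"):
            raise ValueError("consumption basis must be 'net' or 'gross'")


@dataclass
class DrawArtifacts:
    """Everything one Monte Carlo draw produced before discounting."""

    draw_index: int
    scenario: _scenarios.ScenarioDraw
    temperature: np.ndarray  # baseline anomaly 2020-2300
    gsl: np.ndarray  # baseline global mean sea level 2020-2300
    md_fixed: dict  # sector -> MD_t for discount-free sectors
    gross_gdppc: np.ndarray
    baseline_fixed_total: np.ndarray  # world damages of non-coastal sectors
    # coastal pieces are (rho, eta)-dependent; closures evaluate them
    coastal_md: dict  # DiscountSpec -> MD_t
    coastal_baseline_total: dict  # DiscountSpec -> world damages
    floored_years: int = 0
    uncapped_mortality: int = 0


@dataclass
class SccResult:
    spec: DiscountSpec
    draws: pd.DataFrame  # per-draw total and partial SC-CO2, 2020 USD/tCO2
    mean: float
    quantiles: dict
    near_term_rate_pct: float
    n_failed: int
    metadata: dict
    paths: dict | None = None  # optional arrays: temperature, gsl, md, sdf


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "mode": config.mode,
            "n_draws": config.n_draws,
            "master_seed": config.master_seed,
            "near_term_rate": config.near_term_rate,
            "sectors": list(config.sectors),
            "pulse": [config.pulse.year, config.pulse.mass_mtc],
            "n_countries": config.n_countries,
            "n_segments": config.n_segments,
            "consumption_basis": config.consumption_basis,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _prepare_shared(config: RunConfig, seed: int):
    from . import fixtures

    gen_config = config.scenario_config or _scenarios.GeneratorConfig(
        n_countries=config.n_countries
    )
    climate_source = config.climate_source
    if climate_source is None:
        climate_source = fixtures.make_climate_ensemble(
            config.n_climate_ensemble, int(substream(seed, "ensemble").integers(2**31))
        )
    elif not isinstance(climate_source, pd.DataFrame):
        climate_source = pd.read_csv(climate_source)
    segments = config.segments
    if segments is None:
        segments = fixtures.make_segments(
            config.n_segments,
            gen_config.n_countries,
            int(substream(seed, "segments").integers(2**31)),
        )
    return gen_config, climate_source, segments


def run_draw(
    config: RunConfig,
    gen_config,
    climate_source,
    draw_index: int,
    seed: int,
    specs,
) -> DrawArtifacts:
    """Run baseline + pulse for one joint parameter draw (common random
    numbers: the pulse run reuses every sampled input)."""
    scen_rng = substream(seed, "mc", draw_index, "scenario")
    if config.scenario_draws:
        scenario = config.scenario_draws[
            int(scen_rng.integers(len(config.scenario_draws)))
        ]
    else:
        scenario = _scenarios.sample_scenario(gen_config, int(scen_rng.integers(2**31)))
    cparams = _climate.sample_climate_params(
        climate_source, seed, keys=("mc", draw_index, "climate")
    )
    slparams = _sealevel.sample_sealevel_params(
        config.sealevel_source, seed, keys=("mc", draw_index, "sealevel")
    )
    beta_m = _damages.sample_mortality_beta(
        config.damage_params, seed, keys=("mc", draw_index, "betaM")
    )
    theta = (
        config.ag_theta_fixed
        if config.ag_theta_fixed is not None
        else _damages.sample_ag_weight(seed, keys=("mc", draw_index, "theta"))
    )

    base = _climate.run_climate(scenario, cparams)
    pulsed = _climate.run_climate(scenario, cparams, pulse=config.pulse)
    years = scenario.years
    T_base = base.slice_years(years[0], years[-1])
    T_pulse = pulsed.slice_years(years[0], years[-1])
    sl_base = _sealevel.run_sealevel(base.temperature, base.years, slparams)
    sl_pulse = _sealevel.run_sealevel(pulsed.temperature, pulsed.years, slparams)

    gross_gdppc = scenario.world_gdppc()

    fixed_sectors = [s for s in config.sectors if s != "coastal"]
    md_fixed, baseline_fixed_total = {}, np.zeros(years.size)
    dp = config.damage_params
    slices_b, slices_p = {}, {}
    for sector in fixed_sectors:
        if sector == "energy":
            slices_b[sector] = _damages.energy_damages(scenario, T_base, dp.energy_beta, dp)
            slices_p[sector] = _damages.energy_damages(scenario, T_pulse, dp.energy_beta, dp)
        elif sector == "mortality":
            slices_b[sector] = _damages.mortality_damages(scenario, T_base, beta_m, dp)
            slices_p[sector] = _damages.mortality_damages(scenario, T_pulse, beta_m, dp)
        elif sector == "agriculture":
            slices_b[sector] = _damages.agriculture_damages(scenario, T_base, theta, dp)
            slices_p[sector] = _damages.agriculture_damages(scenario, T_pulse, theta, dp)
    for sector in fixed_sectors:
        baseline_fixed_total += slices_b[sector].total()
    md_fixed = marginal_damage_path(slices_b, slices_p, config.pulse)

    coastal_md, coastal_baseline_total = {}, {}
    if "coastal" in config.sectors:
        for spec in specs:
            # planning discounts with the run's (rho, eta) on gross growth
            df = sdf_path(gross_gdppc, spec, years)
            cb = _coastal.coastal_sector_damages(
                config._segments_arr, sl_base, scenario, df, config.cost_params
            )
            cp_ = _coastal.coastal_sector_damages(
                config._segments_arr, sl_pulse, scenario, df, config.cost_params
            )
            coastal_md[spec] = marginal_damage_path(
                {"coastal": cb}, {"coastal": cp_}, config.pulse
            )["coastal"]
            coastal_baseline_total[spec] = cb.total()

    uncapped = slices_b.get("mortality")
    return DrawArtifacts(
        draw_index=draw_index,
        scenario=scenario,
        temperature=T_base,
        gsl=sl_base.slice_years(years[0], years[-1]),
        md_fixed=md_fixed,
        gross_gdppc=gross_gdppc,
        baseline_fixed_total=baseline_fixed_total,
        coastal_md=coastal_md,
        coastal_baseline_total=coastal_baseline_total,
        uncapped_mortality=uncapped.uncapped_country_years if uncapped else 0,
    )


def _summarize(spec, rows, paths, config, n_failed, c_paths, years) -> SccResult:
    draws = pd.DataFrame(rows)
    totals = draws["scc_total"].to_numpy()
    return SccResult(
        spec=spec,
        draws=draws,
        mean=float(totals.mean()),
        quantiles={
            p: float(np.quantile(totals, p, method="linear")) for p in QUANTILE_PROBS
        },
        near_term_rate_pct=near_term_rate(spec, c_paths, years),
        n_failed=n_failed,
        metadata={
            "master_seed": config.master_seed,
            "n_draws": config.n_draws,
            "rho": spec.rho,
            "eta": spec.eta,
            "config_hash": _config_hash(config),
            "pulse_mass_mtc": config.pulse.mass_mtc,
            "units": "2020 USD per tonne CO2",
        },
        paths=paths if config.store_paths else None,
    )


def run_monte_carlo(
    n_draws: int,
    spec: DiscountSpec | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
    specs: list | None = None,
):
    """Monte Carlo SC-CO2.  With ``specs`` (a list of DiscountSpec), heavy
    per-draw artifacts are shared across discounting schemes and a dict
    {spec: SccResult} is returned; otherwise a single SccResult.

    Per draw the scenario, climate and sea-level parameters, the mortality
    coefficients and the agriculture weight are jointly sampled; baseline
    and pulse runs share all of them.  Draw failures are tolerated up to 1%.
    """
    config = config or RunConfig()
    config = replace(config, n_draws=n_draws, master_seed=seed)
    config.validate()
    single = specs is None
    if single:
        spec = spec or discount_spec_for_rate(config.near_term_rate)
        specs = [spec]

    gen_config, climate_source, segments = _prepare_shared(config, seed)
    config._segments_arr = _coastal._SegmentArrays(segments)
    config.segments = segments

    years = _scenarios.YEARS
    rows = {sp: [] for sp in specs}
    c_paths = {sp: [] for sp in specs}
    paths = {
        sp: {"temperature": [], "gsl": [], "md": [], "sdf": []} for sp in specs
    }
    failures = []
    for d in range(n_draws):
        try:
            art = run_draw(config, gen_config, climate_source, d, seed, specs)
        except Exception as exc:  # noqa: BLE001 - per-draw isolation
            failures.append((d, repr(exc)))
            if len(failures) > max(1, 0.01 * n_draws):
                raise RuntimeError(
                    f"more than 1% of draws failed; first failures: {failures[:3]}"
                ) from exc
            continue
        for sp in specs:
            md = dict(art.md_fixed)
            baseline_total = art.baseline_fixed_total.copy()
            if "coastal" in config.sectors:
                md["coastal"] = art.coastal_md[sp]
                baseline_total += art.coastal_baseline_total[sp]
            if config.consumption_basis == "net":
                c, floored = consumption_path(
                    art.scenario, baseline_total, config.consumption_floor
                )
            else:
                c, floored = consumption_path(
                    art.scenario, np.zeros(years.size), config.consumption_floor
                )
            sdf = sdf_path(c, sp, years)
            md_total = sum(md.values())
            row = {
                "draw": art.draw_index,
                "scc_total": scc_from_draw(md_total, sdf),
                "floored_years": floored,
                "uncapped_mortality": art.uncapped_mortality,
            }
            for sector in config.sectors:
                row[f"scc_{sector}"] = partial_scc(sector, md, sdf)
            rows[sp].append(row)
            c_paths[sp].append(c)
            if config.store_paths:
                paths[sp]["temperature"].append(art.temperature)
                paths[sp]["gsl"].append(art.gsl)
                paths[sp]["md"].append(md_total)
                paths[sp]["sdf"].append(sdf)

    if not any(rows.values()):
        raise RuntimeError("all draws failed")
    results = {}
    for sp in specs:
        p = {k: np.asarray(v) for k, v in paths[sp].items()} if config.store_paths else None
        if p is not None:
            p["years"] = years.copy()
        results[sp] = _summarize(
            sp, rows[sp], p, config, len(failures), np.asarray(c_paths[sp]), years
        )
    return results[specs[0]] if single else results
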