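"""Energy, mortality and agriculture damage functions.

Energy: change in energy expenditure as a share of GDP is linear in the
global temperature anomaly with a through-origin regional coefficient.
Mortality: excess deaths are a regional fractional change in all-cause
mortality per degree applied to baseline deaths, monetized with an
income-scaled value of a statistical life (VSL).  Agriculture: a regional
piecewise-linear welfare-cost function of warming (knots at 1/2/3 K,
low/central/high parameterizations blended by a triangular weight), scaled
by the 1990 agricultural GDP share and an income factor.

Default coefficient tables are synthetic-but-plausible placeholders (the
real ones live in the underlying studies' supplements) and are fully
overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seeds import substream

N_ENERGY_REGIONS = 12
N_MORTALITY_REGIONS = 10
N_AG_REGIONS = 16

SECTORS = ("energy", "mortality", "agriculture", "coastal")

# synthetic-but-plausible defaults ------------------------------------------

DEFAULT_ENERGY_BETA = np.array(
    [0.0021, 0.0008, 0.0015, 0.0027, 0.0005, 0.0012,
     0.0032, 0.0018, 0.0009, 0.0024, 0.0014, 0.0011]
)  # share of GDP per K, 12 regions

DEFAULT_MORTALITY_BETA_MEAN = np.array(
    [0.008, 0.021, 0.035, 0.012, -0.004, 0.027,
     0.044, 0.016, 0.006, 0.030]
)  # fractional change in all-cause mortality per K, 10 regions
DEFAULT_MORTALITY_BETA_SE = np.array(
    [0.004, 0.008, 0.012, 0.005, 0.006, 0.010,
     0.015, 0.007, 0.004, 0.011]
)

DEFAULT_AG_SIGMA = np.linspace(0.03, 0.30, N_AG_REGIONS)  # 1990 ag share of GDP

# welfare cost as a fraction of the ag-share base at 1, 2, 3 K (low/central/high)
_AG_CENTRAL = np.array([0.01, 0.035, 0.08])
_AG_LOW = np.array([-0.015, -0.005, 0.02])
_AG_HIGH = np.array([0.03, 0.09, 0.18])


def default_ag_knots() -> np.ndarray:
    """(region, parameterization{low,central,high}, knot{1,2,3K}) table with
    mild regional scaling around the central shapes."""
    scale = np.linspace(0.6, 1.5, N_AG_REGIONS)[:, None]
    return np.stack(
        [scale * _AG_LOW, scale * _AG_CENTRAL, scale * _AG_HIGH], axis=1
    )


def default_region_maps(n_countries: int) -> dict:
    """Deterministic country -> region index maps per sector."""
    idx = np.arange(n_countries)
    return {
        "energy": idx % N_ENERGY_REGIONS,
        "mortality": idx % N_MORTALITY_REGIONS,
        "agriculture": idx % N_AG_REGIONS,
    }


@dataclass
class DamageParams:
    energy_beta: np.ndarray = field(default_factory=lambda: DEFAULT_ENERGY_BETA.copy())
    mortality_beta_mean: np.ndarray = field(
        default_factory=lambda: DEFAULT_MORTALITY_BETA_MEAN.copy()
    )
    mortality_beta_se: np.ndarray = field(
        default_factory=lambda: DEFAULT_MORTALITY_BETA_SE.copy()
    )
    vsl_base: float = 10.05e6  # USD, US reference in 2020
    vsl_ref_gdppc: float = 63_000.0  # US GDP per capita in 2020, USD
    vsl_income_elasticity: float = 1.0
    ag_sigma: np.ndarray = field(default_factory=lambda: DEFAULT_AG_SIGMA.copy())
    ag_income_elasticity: float = 0.31
    ag_knots: np.ndarray = field(default_factory=default_ag_knots)
    # 1990 income approximated as 2020 income over the 1990-2020 growth factor
    ag_1990_income_factor: float = 1.6
    region_maps: dict | None = None

    def validate(self) -> None:
        if ((self.ag_sigma < 0) | (self.ag_sigma > 1)).any():
            raise ValueError("agriculture GDP shares must lie in [0, 1]")
        if (self.mortality_beta_se < 0).any():
            raise ValueError("mortality standard errors must be >= 0")

    def maps_for(self, n_countries: int) -> dict:
        maps = self.region_maps or default_region_maps(n_countries)
        for sector, m in maps.items():
            if len(m) != n_countries:
                raise ValueError(
                    f"{sector} region map covers {len(m)} countries, need {n_countries}"
                )
        return maps


@dataclass
class SectorDamageSlice:
    """Damages for one sector at its native resolution."""

    sector: str
    years: np.ndarray
    region_labels: list
    damages: np.ndarray  # (n_regions_or_countries, n_years), USD/yr
    excess_deaths: np.ndarray | None = None  # mortality only
    uncapped_country_years: int = 0  # diagnostic: excess > baseline deaths

    def total(self) -> np.ndarray:
        return self.damages.sum(axis=0)


# ---------------------------------------------------------------------------
# energy


def fit_energy_coefficients(tables: dict) -> np.ndarray:
    """Through-origin least squares per region: beta = sum(xy)/sum(x^2).

    ``tables`` maps region index -> array of (temperature K, expenditure
    share change) rows.
    """
    betas = np.zeros(max(tables) + 1)
    for region, pts in tables.items():
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < 2:
            raise ValueError(f"region {region}: need >= 2 response points")
        x, y = pts[:, 0], pts[:, 1]
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            raise ValueError(f"region {region}: all temperatures zero, fit undefined")
        betas[region] = float(np.sum(x * y)) / sxx
    return betas


def energy_damages(draw, temperature: np.ndarray, beta: np.ndarray,
                   params: DamageParams) -> SectorDamageSlice:
    """Country-level energy damages: fraction = beta_region * T, dollars =
    fraction * GDP.  ``temperature`` is the anomaly over the draw years."""
    maps = params.maps_for(len(draw.countries))["energy"]
    frac = beta[maps][:, None] * temperature[None, :]
    dollars = frac * draw.population * draw.gdppc
    return SectorDamageSlice("energy", draw.years, list(draw.countries), dollars)


# ---------------------------------------------------------------------------
# mortality


def sample_mortality_beta(params: DamageParams, seed: int,
                          *, keys: tuple = ("mortality",)) -> np.ndarray:
    """Regional coefficients drawn from N(point estimate, SE)."""
    rng = substream(seed, *keys)
    return rng.normal(params.mortality_beta_mean, params.mortality_beta_se)


def value_of_statistical_life(gdppc: np.ndarray, params: DamageParams) -> np.ndarray:
    """Income-scaled VSL: base * (gdppc / reference gdppc)^elasticity."""
    return params.vsl_base * (
        np.asarray(gdppc, float) / params.vsl_ref_gdppc
    ) ** params.vsl_income_elasticity


def mortality_damages(draw, temperature: np.ndarray, beta_draw: np.ndarray,
                      params: DamageParams) -> SectorDamageSlice:
    """Excess deaths = beta_region * T * population * baseline rate,
    monetized at the country-year VSL (identity dollars/deaths = VSL)."""
    if (draw.mortality_rate < 0).any():
        raise ValueError("baseline mortality rate must be non-negative")
    maps = params.maps_for(len(draw.countries))["mortality"]
    baseline_deaths = draw.population * draw.mortality_rate
    excess = beta_draw[maps][:, None] * temperature[None, :] * baseline_deaths
    vsl = value_of_statistical_life(draw.gdppc, params)
    dollars = vsl * excess
    uncapped = int((excess > baseline_deaths).sum())
    return SectorDamageSlice(
        "mortality", draw.years, list(draw.countries), dollars,
        excess_deaths=excess, uncapped_country_years=uncapped,
    )


# ---------------------------------------------------------------------------
# agriculture


def sample_ag_weight(seed: int, *, keys: tuple = ("agweight",)) -> float:
    """Triangular(0, mode 0.5, 1) blending weight."""
    return float(substream(seed, *keys).triangular(0.0, 0.5, 1.0))


def blend_ag_knots(knots: np.ndarray, theta: float) -> np.ndarray:
    """Linear blend of the two parameterizations nearest to theta, with
    anchors low=0, central=0.5, high=1."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    low, central, high = knots[:, 0, :], knots[:, 1, :], knots[:, 2, :]
    if theta <= 0.5:
        w = theta / 0.5
        return (1.0 - w) * low + w * central
    w = (theta - 0.5) / 0.5
    return (1.0 - w) * central + w * high


def ag_cost_fraction(knot_values: np.ndarray, temperature: np.ndarray) -> np.ndarray:
    """Piecewise-linear f(T) through (0,0) and knots at 1/2/3 K, with the
    final segment extended beyond 3 K; negative T clamped to 0 with a
    warning (fraction may be negative: benefits)."""
    T = np.asarray(temperature, dtype=float)
    if (T < 0).any():
        warnings.warn("negative temperature anomaly clamped to 0 in agriculture")
        T = np.maximum(T, 0.0)
    k1, k2, k3 = knot_values[:, 0:1], knot_values[:, 1:2], knot_values[:, 2:3]
    Tb = T[None, :]
    seg0 = k1 * Tb
    seg1 = k1 + (k2 - k1) * (Tb - 1.0)
    seg2 = k2 + (k3 - k2) * (Tb - 2.0)
    seg3 = k3 + (k3 - k2) * (Tb - 3.0)  # extended final slope
    out = np.where(Tb <= 1.0, seg0, np.where(Tb <= 2.0, seg1,
                   np.where(Tb <= 3.0, seg2, seg3)))
    return out


def _region_aggregate(draw, maps: np.ndarray, n_regions: int):
    """Population, GDP and pop-weighted gdppc at region resolution."""
    n_years = draw.years.size
    pop = np.zeros((n_regions, n_years))
    gdp = np.zeros((n_regions, n_years))
    np.add.at(pop, maps, draw.population)
    np.add.at(gdp, maps, draw.population * draw.gdppc)
    gdppc = gdp / np.maximum(pop, 1e-12)
    return pop, gdp, gdppc


def agriculture_damages(draw, temperature: np.ndarray, theta: float,
                        params: DamageParams) -> SectorDamageSlice:
    """Region-level agricultural welfare costs:
    AgPctCost = sigma * (gdppc_t / gdppc_1990)^(-elasticity) * f_theta(T)."""
    params.validate()
    maps = params.maps_for(len(draw.countries))["agriculture"]
    n_regions = len(params.ag_sigma)
    pop, gdp, gdppc = _region_aggregate(draw, maps, n_regions)
    populated = pop > 0  # regions with no mapped countries contribute zero
    gdppc_1990 = gdppc[:, 0:1] / params.ag_1990_income_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        income_factor = (gdppc / gdppc_1990) ** (-params.ag_income_elasticity)
    income_factor = np.where(populated, income_factor, 0.0)
    f = ag_cost_fraction(blend_ag_knots(params.ag_knots, theta), temperature)
    pct = params.ag_sigma[:, None] * income_factor * f
    dollars = pct * gdp
    labels = [f"agri-{j:02d}" for j in range(n_regions)]
    return SectorDamageSlice("agriculture", draw.years, labels, dollars)
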