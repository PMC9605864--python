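"""Synthetic input bundles: toy climate parameter ensemble, sea-level prior
configuration, coastal segments, damage-coefficient tables, historical
emissions and exogenous forcing series.

Everything here is generated programmatically and deterministically from a
seed; `make_fixtures` writes the bundle to CSV/YAML so the file-loading
paths of every module can be exercised and a run is reproducible from
artifacts on disk.  The tables are synthetic-but-plausible stand-ins for
the calibrated inputs of the real studies and are clearly labelled as such.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as _climate
from . import coastal as _coastal
from . import damages as _damages
from . import sealevel as _sealevel
from .seeds import substream


def make_climate_ensemble(n: int, seed: int) -> pd.DataFrame:
    """Toy calibrated-parameter ensemble: independent spreads around the
    default simple-climate-model constants, pool fractions renormalized."""
    rng = substream(seed, "fixtures", "climate")
    base = _climate.ClimateParams()
    a = np.maximum(base.a[None, :] * np.exp(rng.normal(0, 0.08, (n, 4))), 1e-4)
    a /= a.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        {
            "a1": a[:, 0], "a2": a[:, 1], "a3": a[:, 2], "a4": a[:, 3],
            "tau2": base.tau[1] * np.exp(rng.normal(0, 0.15, n)),
            "tau3": base.tau[2] * np.exp(rng.normal(0, 0.15, n)),
            "tau4": base.tau[3] * np.exp(rng.normal(0, 0.15, n)),
            "r0": rng.normal(base.r0, 3.0, n),
            "rU": np.maximum(rng.normal(base.rU, 0.004, n), 0.0),
            "rT": np.maximum(rng.normal(base.rT, 0.8, n), 0.0),
            "F2x": rng.normal(base.F2x, 0.2, n),
            "q1": np.maximum(rng.normal(base.q[0], 0.06, n), 0.05),
            "q2": np.maximum(rng.normal(base.q[1], 0.12, n), 0.05),
            "d1": np.maximum(rng.normal(base.d[0], 30.0, n), 50.0),
            "d2": np.maximum(rng.normal(base.d[1], 0.8, n), 1.5),
        }
    )
    return df


def make_segments(n: int, n_countries: int, seed: int) -> list:
    """Synthetic coastal-segment database (a stand-in for a real coastal
    vulnerability database): lognormal lengths and densities, mixed-sign
    GEV shapes, and mild spread in unit costs and sea-level scalings."""
    rng = substream(seed, "fixtures", "segments")
    segments = []
    for i in range(n):
        segments.append(
            _coastal.CoastalSegment(
                segment_id=f"seg{i:05d}",
                length_km=float(np.exp(rng.normal(3.0, 0.8))),
                slope_m_per_km=float(np.exp(rng.normal(0.7, 0.6))),
                pop_density=float(np.exp(rng.normal(4.5, 1.2))),
                country_index=int(rng.integers(0, n_countries)),
                gev_loc=float(rng.uniform(0.5, 2.5)),
                gev_scale=float(np.exp(rng.normal(-1.2, 0.5))),
                gev_shape=float(np.clip(rng.normal(0.05, 0.08), -0.3, 0.4)),
                protect_cost=float(np.exp(rng.normal(14.5, 0.5))),  # USD/km/m
                reloc_cost=float(np.exp(rng.normal(9.5, 0.4))),  # USD/person
                slr_scaling=float(np.clip(rng.normal(1.0, 0.15), 0.3, 1.7)),
            )
        )
    return segments


def make_damage_tables(n_countries: int) -> dict:
    """Per-sector coefficient tables and country->region maps as frames."""
    maps = _damages.default_region_maps(n_countries)
    knots = _damages.default_ag_knots()
    return {
        "energy": pd.DataFrame(
            {
                "region": np.arange(_damages.N_ENERGY_REGIONS),
                "beta_share_of_gdp_per_K": _damages.DEFAULT_ENERGY_BETA,
            }
        ),
        "mortality": pd.DataFrame(
            {
                "region": np.arange(_damages.N_MORTALITY_REGIONS),
                "beta_frac_mortality_per_K": _damages.DEFAULT_MORTALITY_BETA_MEAN,
                "beta_se": _damages.DEFAULT_MORTALITY_BETA_SE,
            }
        ),
        "agriculture": pd.DataFrame(
            {
                "region": np.arange(_damages.N_AG_REGIONS),
                "ag_share_gdp_1990": _damages.DEFAULT_AG_SIGMA,
                **{
                    f"{lvl}_{k}K": knots[:, j, k - 1]
                    for j, lvl in enumerate(("low", "central", "high"))
                    for k in (1, 2, 3)
                },
            }
        ),
        "region_map": pd.DataFrame(
            {
                "country_index": np.arange(n_countries),
                "energy_region": maps["energy"],
                "mortality_region": maps["mortality"],
                "agriculture_region": maps["agriculture"],
            }
        ),
    }


def make_fixtures(out_dir, seed: int = 0, *, n_ensemble: int = 100,
                  n_segments: int = 500, n_countries: int = 184) -> dict:
    """Write the full synthetic input bundle; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    ensemble = make_climate_ensemble(n_ensemble, seed)
    files["climate_ensemble"] = out / "climate_ensemble.csv"
    ensemble.to_csv(files["climate_ensemble"], index=False)

    priors = {
        name: {"kind": kind, "args": [float(a) for a in args]}
        for name, (kind, args) in _sealevel.DEFAULT_PRIORS.items()
    }
    files["sealevel_priors"] = out / "sealevel_priors.yaml"
    files["sealevel_priors"].write_text(yaml.safe_dump(priors))

    segments = make_segments(n_segments, n_countries, seed)
    files["segments"] = out / "coastal_segments.csv"
    _coastal.segments_to_frame(segments).to_csv(files["segments"], index=False)

    for name, df in make_damage_tables(n_countries).items():
        files[f"damage_{name}"] = out / f"damage_{name}.csv"
        df.to_csv(files[f"damage_{name}"], index=False)

    hist_years = np.arange(_climate.HIST_YEAR_START, 2020)
    hist = _climate.historical_emissions(hist_years)
    files["historical_emissions"] = out / "historical_emissions.csv"
    pd.DataFrame(
        {"year": hist_years, "co2_gtco2": hist["co2"], "ch4_mt": hist["ch4"],
         "n2o_mt": hist["n2o"]}
    ).to_csv(files["historical_emissions"], index=False)

    years = np.arange(_climate.HIST_YEAR_START, _climate.YEAR_END + 1)
    files["exogenous_forcing"] = out / "exogenous_forcing.csv"
    pd.DataFrame(
        {"year": years, "forcing_wm2": _climate.exogenous_forcing(years)}
    ).to_csv(files["exogenous_forcing"], index=False)

    return files


def load_sealevel_priors(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    return {name: (spec["kind"], tuple(spec["args"])) for name, spec in raw.items()}


def degenerate_run_config(n_countries: int = 10, n_segments: int = 20):
    """A run configuration with every source of uncertainty switched off:
    point-mass scenario anchors, a single climate parameter set, point
    sea-level priors, zero mortality SEs and a fixed agriculture weight."""
    from . import scenarios as _scenarios
    from . import valuation as _valuation

    anchor = _scenarios.QuantileAnchor
    gen = _scenarios.GeneratorConfig(
        pop_2300=anchor(7.3e9, 7.3e9, 7.3e9),
        pop_peak_log_sd=0.0,
        pop_peak_year_sd=0.0,
        growth=anchor(0.0088, 0.0088, 0.0088),
        growth_noise_sd=0.0,
        co2_2100=anchor(17.0, 17.0, 17.0),
        ch4_log_sd=0.0,
        n2o_log_sd=0.0,
        n_countries=n_countries,
        country_income_log_sd=0.0,
        share_dirichlet_concentration=np.inf,
    )
    point_priors = {
        name: ("uniform", (args[0], args[0]))
        if kind == "uniform"
        else (kind, (args[0], 0.0))
        for name, (kind, args) in _sealevel.DEFAULT_PRIORS.items()
    }
    dp = _damages.DamageParams(
        mortality_beta_se=np.zeros_like(_damages.DEFAULT_MORTALITY_BETA_SE)
    )
    ensemble = make_climate_ensemble(1, 0)
    return _valuation.RunConfig(
        n_countries=n_countries,
        n_segments=n_segments,
        scenario_config=gen,
        climate_source=ensemble,
        sealevel_source=point_priors,
        damage_params=dp,
        ag_theta_fixed=0.5,
        store_paths=False,
    )
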