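# sccarbon

`sccarbon` is a probabilistic integrated-assessment engine for estimating
the **social cost of carbon dioxide (SC-CO₂)** — the present value, per
tonne of CO₂ emitted, of all future monetized damages that tonne causes.
It is aimed at environmental economists and climate-policy analysts who
need a transparent, fully seeded Monte Carlo SC-CO₂ pipeline with sectoral
decomposition.

## What it computes

For each Monte Carlo draw the engine samples a joint socioeconomic and
emissions scenario, climate and sea-level model parameters, and damage
function coefficients, then runs the chain twice — a baseline and a run
that is identical except for a 0.1 MtC CO₂ pulse in 2020:

1. **Scenarios** — country-level population and GDP per capita plus global
   CO₂/CH₄/N₂O emissions, 2020–2300, quantile-anchored to published
   probabilistic projections (median world population peaking near 11
   billion and declining to 7.3 billion by 2300; median cumulative-average
   per-capita growth 0.88 %/yr; median 2100 net CO₂ emissions 17 GtCO₂/yr),
   with growth–emissions dependence via a Gaussian copula.
2. **Climate** — a four-pool impulse-response carbon cycle whose timescales
   scale with warming and cumulative sink uptake (the iIRF100 closure),
   logarithmic CO₂ + square-root CH₄/N₂O forcing, and a two-box thermal
   response.
3. **Sea level** — component contributions (thermal expansion, glaciers,
   Greenland, Antarctica with a fast-disintegration tipping threshold,
   land-water storage) downscaled to coastal segments by static scaling
   factors.
4. **Damages** — four sectors: building energy expenditures
   (`ΔE/GDP = βᴱⱼ·Tₜ`), temperature-related mortality (excess deaths
   `βᴹⱼ·Tₜ·pop·mortality rate`, monetized at an income-scaled value of a
   statistical life, US 2020 base $10.05M, elasticity ε = 1), agriculture
   (regional piecewise-linear welfare functions of warming with knots at
   1/2/3 K, triangular-blended parameterizations, income elasticity
   ϵ = 0.31), and coastal impacts from a deterministic least-cost
   adaptation model (retreat / protect / no adaptation against local sea
   level and GEV storm surge).
5. **Valuation** — stochastic Ramsey discounting
   `SDF_t = (1+ρ)^−(t−2020) · (c_t/c_2020)^−η`, marginal damages
   `MD_t = Σ_sectors (damages with pulse − baseline) / pulse tCO₂`, and
   `SC-CO₂ = Σ_t SDF_t · MD_t` in 2020 USD/tCO₂, with per-sector partial
   SC-CO₂ values that sum exactly to the total.  Packaged (ρ, η) pairs
   correspond to near-term discount rates of 1.5 % (0.01 %, 1.02), 2 %
   (0.2 %, 1.24), 2.5 % (0.5 %, 1.42) and 3 % (0.8 %, 1.57).

By default the engine runs on bundled synthetic inputs (a toy climate
parameter ensemble, a sea-level prior sampler, synthetic coastal segments
and placeholder damage tables); every loader also accepts deposited real
inputs (`mode="data"`), which are required for reproducing published
headline values.

## Worked example

```sh
$ sccarbon scc --draws 100 --seed 2020 --near-term-rate 2.0 \
      --countries 184 --segments 500 --out scc_run
sccarbon 0.1.0 | config f33fe401b4eff9ea | 100 draws in 37.8 s
mean SC-CO2 = $133.23/tCO2 (5-95%: $51.96 to $235.10) at a 2.19% near-term rate
wrote scc_run/scc_draws.csv
wrote scc_run/run_metadata.json
wrote scc_run/paths.nc
```

The mean is the expected SC-CO₂ across the 100 joint draws under the 2 %
near-term discounting scheme; the 5–95 % range reflects the compounding
scenario, climate, sea-level and damage-function uncertainty; the realized
near-term rate is the cross-draw average of r_t = ρ + η·g_t over the first
decade.  `scc_draws.csv` holds per-draw totals and the partial SC-CO₂ for
each sector (energy, mortality, agriculture, coastal); `paths.nc` stores
the per-draw temperature, sea-level, marginal-damage and discount-factor
paths.

Library use mirrors the CLI:

```python
from sccarbon import RunConfig, run_monte_carlo
result = run_monte_carlo(100, config=RunConfig(), seed=2020)
print(result.mean, result.quantiles)
```

## Layout

- `src/sccarbon/scenarios.py` — scenario generator, quantiles, CSV IO
- `src/sccarbon/climate.py` — carbon cycle, forcing, thermal response
- `src/sccarbon/sealevel.py` — sea-level components and downscaling
- `src/sccarbon/damages.py` — energy / mortality / agriculture damages
- `src/sccarbon/coastal.py` — least-cost coastal adaptation
- `src/sccarbon/valuation.py` — discounting, SC-CO₂, Monte Carlo driver
- `src/sccarbon/fixtures.py`, `cli.py`, `outputs.py` — inputs, CLI, IO
- `docs/methods.md` — model description, parameter choices, limitations
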