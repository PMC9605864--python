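# Methods

This note documents the models implemented in `sccarbon`, the choices made
where the design was genuinely open, and what the synthetic defaults do and
do not represent.

## Scenario generator

The generator emulates the statistical structure of multi-century
probabilistic socioeconomic projections.  Three headline scalars are
anchored at printed 5/50/95 quantiles and sampled through **two-piece
(split) normal / lognormal transforms**, which pass through all three
anchors exactly even when the printed range is asymmetric:

- world population in 2300 (split lognormal; default anchors 2.8/7.3/21
  billion), embedded in a logistic-rise-then-exponential-decline world
  trajectory whose peak level (median 11 billion) and peak year (median
  2130, sd 30 yr) are sampled jointly with the terminal level;
- cumulative-average world per-capita growth 2020–2300 (split normal;
  0.17/0.88/2.7 %/yr).  Log GDP-per-capita increments equal the sampled
  base rate plus a zero-sum declining tilt and zero-sum noise, so the
  geometric-average growth of every draw equals its sampled rate exactly;
- net CO₂ emissions in 2100 (split normal; −7/17/62 GtCO₂/yr), reached
  linearly from 42 GtCO₂/yr in 2020, then declining at 0.04 GtCO₂/yr² with
  a −25 GtCO₂/yr floor.

The growth–emissions link is a **Gaussian copula**: the emissions z-score
is correlated with the growth z-score with coefficient equal to the
configured sensitivity (default 0.5).  This preserves the emissions
marginal exactly while producing the documented positive rank correlation;
setting the sensitivity to zero decouples the two.  An intensity-decline
generative story was considered and rejected because it cannot hit
asymmetric quantile anchors without an outer calibration loop.  Other
variables are independent — the joint distribution beyond the
growth–emissions link is not constrained by the published projections.

Country detail: population shares follow a slow Dirichlet random walk
(concentration 5,000, decade steps, annually interpolated and
renormalized, floored at 1e-9 so tiny countries never vanish); relative
incomes start lognormal (sd 1.0) and converge toward the world level with
a 150-yr e-folding time, renormalized each year so the population-weighted
mean reproduces the anchored world path exactly.  Baseline all-cause
mortality rates are a deterministic declining function of income,
`0.0025 + 0.0713 · gdppc^−0.3` (≈7.7 per 1,000 at $10k), clipped to
(1e-4, 0.5).  CH₄ and N₂O follow anchor paths scaled by a lognormal
multiplier.  The default 184 countries match the study resolution; tests
use fewer because world-level behaviour is unchanged.

What the generator does **not** emulate: cohort demography, survey-based
expert weights, within-country heterogeneity, emissions-policy regime
switching.  Passing calibration tests shows the anchored quantiles are
reproduced, not that country-level joint behaviour matches real data.

## Climate emulator

A four-pool impulse-response carbon cycle: pool `i` holds burden `R_i`
(GtC) decaying at timescale `α·τ_i`.  Each year α solves
`iIRF100(α) = r0 + rU·U + rT·T` by bisection (bracket [0.01, 100]; outside
targets are clamped with a warning — iIRF100 saturates at 100 yr by
construction).  Discretization is exact exponential decay with
constant-within-year emissions; cumulative sink uptake `U` absorbs the
non-airborne carbon, so the budget closes to rounding each step.
Concentration is `C0 + ΣR_i / 2.124` ppm.  Forcing:
`F2x/ln2 · ln(C/C0)` plus square-root CH₄/N₂O terms and a packaged
exogenous series (a middle-of-the-road non-CO₂ pathway: aerosol cooling
fading after 2020).  Temperature: two boxes with exact-decay updates;
equilibrium warming for sustained forcing F is `F·(q1+q2)`.

Default constants (`a = (0.2173, 0.2240, 0.2824, 0.2763)`,
`τ = (1e6, 394.4, 36.54, 4.304)` yr, `r0 = 32.4`, `rU = 0.019` yr/GtC,
`rT = 4.165` yr/K, `F2x = 3.71` W m⁻², `q = (0.33, 0.41)` K/(W m⁻²),
`d = (239, 4.1)` yr) come from the published simple-climate-model
literature and live in an editable config — they are calibration products,
not constants of this package.  The 1750–2019 spin-up uses a synthetic
smooth emissions history scaled to land near 405 ppm and ~1.1 K in 2020.
Parameter uncertainty enters by uniform row sampling from an ensemble
table; the bundled 100-member table spreads each parameter independently
around the defaults, which ignores the posterior correlations a real
calibrated ensemble would carry.

## Sea level

One state variable per component.  Thermal expansion relaxes toward
`s·T` (default s = 0.35 m/K, τ = 400 yr).  Glaciers melt at
`β0 (T − T_eq)(V/V0)^0.65`, bounded so the remaining volume stays in
[0, V0].  Greenland melts at `max(0, γ_G·T)`; Antarctica at `γ_A·T` plus a
fast-disintegration rate λ (default prior U(0, 6) mm/yr) whenever the
Antarctic proxy temperature exceeds an uncertain threshold.  The proxy is
`1.2 ×` the global anomaly — the published model family references
Antarctic surface temperature without fixing its link to global warming,
so the multiplier is an explicit config knob.  Land-water storage is a
linear trend.  Components are referenced to 1900 and the total is exactly
their sum.  Local sea level is the global mean times a time-invariant
segment scaling factor.  Defaults give ≈0.22 m (2020), ≈0.6 m (2100) and
≈1.9 m (2300) under a mid-range warming path.  Bayesian calibration to the
tide-gauge record is out of scope; parameters come from a posterior-style
table or the documented prior sampler.

## Damages

**Energy** — regional through-origin coefficients βᴱ (fit by
`β = Σxy/Σx²` from (temperature, expenditure-share) response tables);
damage fraction `βᴱ·T` times country GDP.  **Mortality** — regional
coefficients sampled `N(point estimate, SE)`; excess deaths
`βᴹ·T·population·baseline rate`; monetized at
`VSL = $10.05M · (gdppc/gdppc_ref)^ε`, ε = 1, reference $63,000 (US 2020).
Excess deaths are deliberately uncapped when they exceed baseline deaths
(the underlying studies are silent); a diagnostic counter reports such
country-years.  **Agriculture** — a triangular(0, 0.5, 1) weight blends
the two nearest of low/central/high piecewise-linear welfare functions
(knots at 1/2/3 K, linear from the origin, final slope extended beyond
3 K — the published figures do not define that region); the cost fraction
is `σ_i · (gdppc_t/gdppc_1990)^−0.31 · f_θ(T)` at 16-region resolution,
with 1990 income approximated as 2020 income divided by 1.6 (the global
1990–2020 growth factor).  Negative anomalies clamp f to zero with a
warning.  Sign is unconstrained: the low parameterization admits benefits.

The default coefficient tables (12 energy and 10 mortality regions, ag
shares 3–30 % of GDP) are synthetic-but-plausible placeholders for the
supplementary tables of the underlying studies, and are overridable; the
country→region maps are deterministic modular assignments.

## Coastal adaptation

Each segment has a linear elevation profile (value per metre of elevation
band = length·density·capital per person / slope, capital = 3× the owning
country's GDP per capita), a GEV surge climatology, and unit costs.
Planning uses 50-year periods with perfect foresight within the period
(the underlying optimization model's horizon is unspecified); in each
period seven strategies are priced — no adaptation; retreat or protect to
the end-of-period local sea level plus the 10/100/1000-yr return level —
and the cheapest NPV wins, ties broken toward no adaptation, then retreat.
Retreat pays relocation plus a 25 % write-off of abandoned value; protect
pays construction (≥ a 0.5 m minimum wall), 1 %/yr maintenance, and
overtopping losses; unprotected segments accrue inundation losses on newly
submerged bands plus expected storm losses (25 % of flooded value).
Expected overtopping uses the closed-form GEV mean-excess tail
approximation `S(c)·(σ+ξ(c−μ))/(1−ξ)` floored at `E[X]−c` (exact below
the support and in the upper tail; a few percent in between), which keeps
the full Monte Carlo inside interactive runtimes.  Coastal NPVs are
discounted with the run's (ρ, η) applied to gross world growth — using
damage-net consumption would make planning circular.  Given a sea-level
path and segments the sector is deterministic.

## Valuation

Consumption defaults to **net** of climate damages,
`c_t = (world GDP − damages)/population`, floored at $100/person/yr with a
logged count of floored years (the gross alternative is a config switch —
the published equation defines only "world average per capita
consumption").  Partials use the total run's SDF so sectoral values add to
the total exactly.  The pulse is 0.1 MtC in 2020; the per-tonne divisor
applies 44/12 exactly once.  All randomness descends from one master seed
through named substreams (per-draw, per-component), so adding draws never
perturbs earlier ones and baseline/pulse runs share every sampled input.
A deflator table (2020 = 1) converts other base years to 2020 USD.

## Problem sizes and numerical choices

Default study conditions: 184 countries, 500 coastal segments, 100-member
climate ensemble, 10,000 generator draws for calibration checks and 100
draws for the end-to-end demonstration runs documented in the README.
Quantiles use the linear-interpolation convention throughout.  Bisection
tolerance for α is 1e-12; carbon-budget closure is asserted at 1e-9 GtC.
Draw failures are isolated and tolerated up to 1 % of the run.

## Known limitations

Synthetic damage tables mean the absolute SC-CO₂ level from the bundled
defaults is illustrative; only runs on the deposited real inputs
(`sccarbon.benchmarks.attempt_benchmarks`) are comparable to published
headline values.  The climate ensemble ignores parameter correlations; the
sea-level components are first-order reductions of the published
semi-empirical forms; coastal costs are a simplified decision structure,
not a re-calibration of the published coastal model; CH₄/N₂O social costs
and equity weighting are out of scope.
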