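# Methods

## The problem

US forests removed carbon from the atmosphere at an increasing rate over
recent decades, and the policy-relevant question is how much of that
increase is *anthropogenic removal* (planting and other management, land
returning to forest, harvest-driven shifts in age structure) versus
*passive uptake* (CO2 fertilization and changing temperature and
precipitation acting on forests that would have stood anyway).
`forestsink` implements a plot-level attribution pipeline for this
question: a growth-and-yield regression with lifetime environmental
exposure covariates, counterfactual volume comparisons, a telescoping
six-driver decomposition of censused inventory change with an explicit
unexplained residual, and conversion of volume changes to live-biomass
carbon.

Because the real inputs (national forest-inventory plot records and
gridded county climate) are large and not redistributable, the package
ships a synthetic-data module that generates all inputs from a fully
specified data-generating process (DGP) with known parameters. Every
stage is validated against that ground truth.

## Yield model

For plot *i* of forest group *g*:

ln V_i = α_g + f(age_i) + Σ_s Σ_{k=1..3} ( β^T_{s,k} T̄_{s,i}^k + β^P_{s,k} P̄_{s,i}^k ) + γ ln C̄_i + FE + ε_i

- **V** — aboveground wood volume density, m³ ha⁻¹. Zero-volume plots
  are dropped before taking logs; the count of dropped plots is recorded
  on the fitted results.
- **f(age)** — per-group age curve. Default is the saturating Clutter
  form −θ_g/age; `ln(age)` and a cubic in age/100 are available as
  robustness alternatives.
- **T̄_s, P̄_s** — *lifetime-mean* seasonal temperature (°C) and
  precipitation (mm): arithmetic means over the inclusive calendar
  window `[year − age + 1, year]`, whose length is exactly the stand
  age. Seasons are meteorological (winter = Dec–Feb of the labelled
  year, spring = Mar–May, summer = Jun–Aug, fall = Sep–Nov); the climate
  table carries one row per (county, season, year). Each variable enters
  as a cubic polynomial in the centred value ((x − c)/scale, scale 1 °C
  for temperature, 100 mm for precipitation) to tame collinearity and
  conditioning; the centres (sample means by default, or fixed values)
  are stored on the fitted results so prediction uses the identical
  basis. Because the constant and all three powers are in the model,
  the choice of centre only reparametrizes the same function space —
  predictions are invariant to it (tested).
- **C̄** — lifetime-mean atmospheric CO2 (ppm), entering in logs, so γ
  is an elasticity: doubling lifetime CO2 multiplies expected volume by
  2^γ.
- **FE** — optional time fixed effects (survey-period bins or year
  dummies), absorbing slow secular drivers such as nitrogen deposition.
  Whether such effects should be period, state×period or year dummies is
  a genuinely open specification question; the package exposes it as
  configuration (`fixed_effects`) rather than fixing one answer, and the
  default fit omits them.
- **ε** — estimation is OLS; the reported covariance is cluster-robust
  by county (CR1), since plots in a county share the same climate
  series.

The lifetime-window convention has sharp observable consequences used as
test anchors: two 100-year-old stands measured in 1960 and 2023 share 37
calendar years of exposure, while 25- and 50-year-old pairs have
disjoint windows separated by 39 and 14 years.

Seasonal climate significance is assessed by a Wald F-test of the three
polynomial coefficients of one (season, variable), using the
cluster-robust covariance block: F = b′S⁻¹b/3 against an F(3, df)
reference.

Cluster inference needs two refinements here, both implemented in the
fit. First, the plain CR1 sandwich is biased downward when regressors
vary mostly *between* clusters — exactly the situation of lifetime
climate means, which are near-constant within a county — so the default
covariance is the bias-reduced **CR2** estimator (each cluster's
residuals rescaled by the inverse symmetric square root of its own
leverage block; exactly unbiased under homoskedasticity). Second, the
cubic polynomial terms are identified disproportionately by the few
counties with extreme climate baselines, so the covariance estimate for
those coefficients behaves as if estimated from far fewer clusters than
exist; confidence intervals and F-tests therefore use
**Bell–McCaffrey/Satterthwaite effective degrees of freedom** (the
minimum component df for the joint test). On the null DGP this brings
the 5%-level seasonal F-test from ~9% rejection (CR1, df = G−1) to
~2–3% — mildly conservative, the known direction of the adjustment —
with near-uniform p-values in the bulk.

## Counterfactual impacts

The impact of a driver subset D ⊆ {temperature, precipitation, CO2} on a
stand of age a in county c at evaluation year y₁ relative to base year
y₀ compares two *comparable* stands — same county, group, age and origin
— whose exposure windows differ: drivers in D use the window ending in
y₁, all others the window ending in y₀. Relative impact is
100·(V_scenario − V_base)/V_base. In the log-linear model, impact
factors multiply exactly over disjoint subsets, and the CO2-only impact
has the closed form (C̄₁/C̄₀)^γ − 1; both identities are tested. County
summaries are unweighted means by default, with optional area weights.

## Six-driver decomposition

A region's model-implied stock is a function of six independent
coordinates, each settable to its start- or end-census state:

1. **area** — per-group total area (ha);
2. **age** — per-group distribution of area over age classes × origins
   (if a group has zero area in one census, its shares are taken from
   the other census, so the whole change loads on the area driver);
3. **temperature**, 4. **precipitation**, 5. **CO2** — the calendar year
   in which every stand's lifetime window ends;
6. **planting** — the planted-minus-natural premium pool, evaluated on a
   census's own planted cells.

Stock = Σ over group × age-class × origin cells of area × predicted
volume at the age-class midpoint (integer midpoint, half rounded up;
class-mean age would be the natural alternative for long classes), plus
the premium pool. The decomposition swaps coordinates from start to end
state one at a time in the order area → age → temperature →
precipitation → CO2 → planting; each contribution is the stock
difference its swap produces. Contributions therefore sum *exactly* to
the explained change, and the unexplained residual (disturbance, pests,
storms, fire, anything the model omits) is the observed census change
minus the explained change.

Two design points deserve emphasis:

- **The planting premium is a separate additive pool**, computed from a
  census's planted areas and the age-interpolated planted-minus-natural
  volume differences, decoupled from the area/age coordinates. The
  planting contribution is then exactly the end-census premium pool
  minus the start-census pool, the whole planted-stand gain is
  attributed to planting rather than leaking into the area and age
  swaps, and telescoping additivity is preserved. A consequence is that
  the planting contribution is identical under every driver order
  (tested).
- **Order dependence is reported, not hidden.** Whether contributions
  should be computed one-at-a-time from the base state (non-additive) or
  by telescoping (additive) is a real convention choice; the package
  telescopes in a fixed default order and provides
  `reorder_sensitivity`, which recomputes contributions under driver
  order permutations (up to all 720) and reports per-driver ranges. The
  explained total is provably order-invariant.

The planted-vs-natural contrast itself is a raw Welch
(unequal-variance) two-sided t-test of volume density within forest
group × age decade (decade d spans ages [d−4, d+5]), using stands up to
50 years, the typical rotation horizon. No matching or covariate
adjustment is applied — the contrast is deliberately the raw management
proxy; an adjusted contrast would be a natural extension. Degenerate
zero-variance equal-mean samples return t = 0, p = 1.

## Carbon reporting

Volume changes (million m³) convert to live-biomass carbon (Tg C,
including coarse roots) by region-specific scalar factors pinned to the
reference regional totals: South 1771/2232, North 786/1025, West 27/54
Tg C per million m³. A full species-level biomass expansion would
require per-species tables outside this package's scope; the pinned
scalars reproduce the reference carbon totals by construction and are
honest about that. The West factor (0.5) differs notably from the other
regions and may partly reflect rounding in the small West totals (54
million m³, 27 Tg C); it is used as-is. Period totals annualize by the
census-year difference (1974–2005 → 31 y, 2005–2022 → 17 y). Passive
share = (temperature + precipitation + CO2) / six-driver total.

The package ships the reference regional contribution tables
(`forestsink.reference`) as reporting inputs. Two southern 2005–2022
entries (temperature, area) are not reported as period totals at the
source and are back-derived from reported per-year rates; they are
flagged `derived` and no validation quantity depends on them.

## Synthetic data-generating process

- **CO2**: piecewise-exponential interpolation through anchor
  concentrations (1850: 285 ppm, 2023: 419 ppm, with the 1960 anchor set
  to 316.49 ppm so that exactly 76.5% of the post-1850 rise falls in
  1960–2023). Constant anchors give a flat series; decreasing anchors
  are rejected.
- **Climate**: each county draws a time-invariant seasonal baseline
  around seasonal normals (T: winter 2, spring 10, summer 22, fall
  12 °C, SD 3; P: 240/280/300/250 mm, SD 60), then follows a linear
  trend plus white noise (T SD 0.9 °C, P SD 45 mm). Default 1960–2023
  shifts: winter +0.7 °C and +15.4 mm; the remaining seasons warm by
  0.4–0.5 °C and precipitation rises in every season except fall
  (spring +8, summer +5, fall −3 mm) — values chosen once as realistic
  magnitudes consistent with the qualitative seasonal pattern, since
  only the winter shifts are quantified in the source material.
- **Plots**: log volume = true yield formula at the plot's lifetime
  exposure + N(0, σ) noise, σ = 0.5 by default (multiplicative
  log-normal volume noise; volumes are positive and the model is in
  logs). True elasticity γ = 1.1, matching the magnitude implied by
  ~26% lifetime-CO2 growth producing ~29% volume gains in young stands.
  Planted plots are drawn only in the three managed softwood groups,
  ages capped at 50, and receive an additive premium interpolated
  through knots that are ~0 at age 10 and near the reported
  planted-vs-natural gaps at age 40 (98.6, 57.6, 77.3 m³ ha⁻¹).
- **Inventories**: random lognormal areas over group × age-class ×
  origin cells at two census years; observed volume is *exactly* the
  area-weighted expected yield (true model at class midpoints, premium
  on planted cells) plus an injected disturbance shock in the end census
  only. By construction a correctly specified decomposition must return
  the shock as its unexplained residual — the pipeline's end-to-end
  identity test.

What the generator does **not** emulate: spatial autocorrelation of
climate or stocking, measurement error in ages, species composition
shifts within groups, disturbance-driven age resets, and non-lognormal
volume noise. Passing tests therefore demonstrate internal correctness
of the estimator and decomposition under a well-specified DGP, not
robustness to the misspecifications real inventory data would add.

## Study conditions and numerical choices

The standing validation experiments (`forestsink.experiments`) run at
5,000 plots (500 per group × 10 groups) spread over 800 counties with
σ = 0.5 — FIA-like sparsity of a handful of same-group plots per county.
The county count matters for inference geometry: seasonal-climate
polynomials are identified almost entirely *across* counties, so the
effective sample for their covariance is the number of counties, not
plots — and for the cubic terms, effectively the few counties with
extreme baselines (see the inference refinements above). Applying the
model to data with few distinct climate locations would push even the
adjusted inference beyond its comfort zone; wild-cluster-bootstrap
p-values would be the remedy there.

Other numerical choices: QR with column pivoting detects rank-deficient
designs and names the collinear columns; under clustering, confidence
intervals and F-tests use the Bell–McCaffrey effective degrees of
freedom (falling back to G−1 where no effective df is available);
age-class midpoints round half up; reorder sensitivity memoizes the 2⁶
driver-state corners (stocks are pure functions of the corner).

## Known limitations

- The decomposition's driver contributions are order-dependent
  (interaction terms are assigned by the substitution order); only the
  explained total and the planting contribution are order-invariant.
  `reorder_sensitivity` quantifies the spread.
- The planting premium is a raw contrast; selection into planting on
  better sites would bias it upward.
- Scalar carbon factors ignore species- and age-dependence of biomass
  expansion.
- CR1 cluster inference needs many climate locations (see above).
- The synthetic DGP cannot validate external realism, only internal
  consistency; headline reference numbers are reproduced through the
  reporting arithmetic, not re-estimated from data.
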