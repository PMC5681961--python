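# Methods

`borealgrowth` implements a complete desk-scale pipeline for analysing how
drought stress, simulated photosynthetic production and stand competition
shape the radial growth of boreal white spruce. This note documents the
models, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Daily climate derivatives

Daily meteorology (tmin, tmax, tmean, precipitation, optional PAR) drives
everything upstream of the tree rings.

* **Vapor pressure deficit.** Saturation vapor pressure follows the Tetens
  curve over water, `e_sat(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa
  (e_sat(30 °C) = 4.243, e_sat(15 °C) = 1.705). With only temperature
  observations available, the daily vapor pressure is taken as `e_sat(tmin)`
  (dewpoint ≈ tmin), so `D = e_sat(tmax) − e_sat(tmin)`, floored at zero. A
  constant-relative-humidity alternative (`vapor_pressure_deficit_rh`) is
  provided because the dewpoint assumption is itself an approximation; a
  single Tetens curve is used at all temperatures for continuity.
* **Degree-day sum (TSUM).** Growing degree-days above a 5 °C base:
  `Σ max(0, tmean − 5)` over a calendar year. The alternative reading —
  summing `tmean` itself on warm days — is rejected; TSUM is a degree-day
  quantity.
* **PAR from solar geometry.** When PAR is not observed it is derived from
  daily extraterrestrial irradiance (declination, sunset hour angle, solar
  constant 1367 W m⁻²), scaled by a bulk atmospheric transmissivity (default
  0.45), a PAR energy fraction of 0.5, and 4.57 μmol J⁻¹, then averaged over
  the daylight period. No orbital-eccentricity correction is applied: the
  annual-mean sun-earth distance keeps the annual integral symmetric between
  hemispheres, and the seasonal ±3% it ignores is far below the uncertainty
  of the fixed-transmissivity assumption.
* **Missing days.** Up to 10 missing days per site-year are linearly
  interpolated (temperature) or zero-filled (precipitation) with a logged
  warning; more invalidate the year rather than being silently imputed.

## Canadian Drought Code

The Drought Code (DC) tracks deep-soil moisture depletion on a 0–800
moisture-equivalent scale Q, with `dc = 400·ln(800/Q)`: 0 is a fully
recharged store, 200 high and ≥300 extreme drought severity. The daily
update is the standard one: precipitation above 2.8 mm becomes effective
rain `0.83·P − 1.27` and recharges Q by `3.937·rain`; potential
evapotranspiration `0.5·max(0, 0.36·(max(tmax, −2.8)+2.8) + L_f(month))`
then deepens the code, with the conventional monthly day-length factors for
≈46° N (May–Oct: 3.8, 5.8, 6.4, 5.0, 2.4, 0.4) used at all sites — the
standard formulation has no latitude adjustment.

The seasonal series runs May 1 – October 31 (184 days). Each year restarts
at a spring start-up value (default 15, the conventional post-thaw value;
0 = fully recharged is available); overwinter carry-over is deliberately not
modeled because the analysis consumes only the **annual maximum** of the
daily series, which is insensitive to modest spring-start differences by
mid-summer. Whether a humidity proxy entered the evapotranspiration term is
left as configuration; the default uses maximum temperature only, as the
standard DC does.

## Photosynthetic production model

Daily canopy gross photosynthetic production is

    A(t) = g·C_a·α·γ / (g + α·γ)

the harmonic combination of a stomatal-diffusion term and a biochemical
term, scaled by ambient CO₂:

* `γ = Q/(Q+δ)` — saturating light response; δ (default 200 μmol m⁻² s⁻¹)
  is the half-saturation.
* `α = α_max/(1+exp(−b·(S−T_s)))` — photosynthetic capacity as a rising
  sigmoid of the acclimated temperature S; the sign convention stores b > 0
  and writes the exponent so capacity shuts down in winter and saturates in
  summer. Defaults: b = 0.5 °C⁻¹, T_s = 8 °C.
* `dS/dt = (T_air − S)/τ` — S is a first-order low-pass filter of daily mean
  air temperature (τ = 8 days), integrated by daily Euler steps; S₀ is the
  first day's temperature, with an optional spin-up replay.
* `g = max(10⁻⁵, α·γ·(√(C_a·10⁻⁶·λ/(1.6·D)) − 1))` — the closed-form
  optimal-stomatal-control conductance with λ = 3000 kPa. Conductance
  reaches the floor once D exceeds the closure threshold
  `D* = C_a·10⁻⁶·λ/1.6` (0.75 kPa at 400 ppm), so warm dry days contribute
  almost nothing. A non-square-root variant of the bracketed term is
  selectable by configuration (`sqrt_conductance=False`) since the two
  readings differ only in that factor.

**Units.** g and α are molar-flux capacities *per unit CO₂ mole fraction*
(mol m⁻² day⁻¹); multiplying the harmonic mean by `C_a·10⁻⁶` gives A in
mol CO₂ m⁻² day⁻¹. This makes the numerical value of α_max large (default
60 000): it was chosen once so a typical boreal site integrates to roughly
40–75 mol m⁻² yr⁻¹ of annual GPP. These parameters are stand-level
calibration constants, not universal ones; real analyses should supply
site-calibrated values through configuration, and all tests pass parameters
explicitly.

Ambient CO₂ rises linearly from 330 to 400 ppm over 1930–2010 (configurable
anchors), flat outside the ramp. The annual integral is taken over the full
calendar year rather than an explicit growing-season window: winter days
contribute ≈0 through the α shutdown, and this avoids an arbitrary season
boundary.

## Ring widths and RCS detrending

Ring series are read and written in Tucson decadal (.rwl) format, with the
measurement dialect auto-detected from the stop marker (999 → 0.01 mm,
−9999 → 0.001 mm), or in a long-form delimited table. Cross-dating quality
is checked by the leave-one-out series–master correlation with a default
acceptance floor of 0.55.

Regional curve standardization builds the expected width at each 1-based
cambial age as the mean across all series (zero-width rings excluded),
truncated where fewer than `min_samples` trees remain, then smoothed by a
centered moving average (default window 10 years) — a deliberately
parameter-light smoother so the curve is exactly reproducible. The tree
ring index is the **residual** `measured − expected` in mm (a ratio option
exists but is off by default), keeping the model's coefficients on the
absolute growth scale. Pith offsets default to zero; stump-height and
breast-height series are pooled. The centered smoother is edge-biased over
the first and last half window; tests therefore validate curve recovery on
interior ages.

RCS rests on staggered germination dates: when all trees in a cohort share
one first year, cambial age is confounded with calendar year and the
regional curve absorbs the common climate signal. The synthetic cohorts
used in testing stagger first years for exactly this reason, and the same
caveat applies to real single-cohort stands.

## Competition metrics

Stand basal area pools all competitor plots in a transect:
`BA = π·Σ(DBH/2000)²/(0.001·n_plots)` m² ha⁻¹ with DBH in mm, split into
deciduous / pine / spruce functional classes (summed before division, so
the total is exactly additive). Trees shorter than breast height carry no
DBH and are excluded. Relative height — the asymmetric-competition proxy —
is height divided by the tallest subject tree in the transect; ties map
to 1. The tallest reference trees sampled separately for potential growth
are excluded from the competitor pool by default (a flag includes them).

## Time-series identification

ACF and CCF delegate to standard estimators (biased-denominator sample
autocorrelations); the CCF sign convention is that a positive lag means the
first series leads. The approximate 95% white-noise band is ±2/√N.

The ESACF table is computed by the Tsay–Tiao iterated autoregression: OLS
AR(k) fits for all needed orders, the coefficient recursion
`φ_i^(k,j) = φ_i^(k+1,j−1) − λ·φ_{i−1}^(k,j−1)` with
`λ = φ_{k+1}^(k+1,j−1)/φ_k^(k,j−1)`, and entry (p, q) equal to the lag-(q+1)
sample autocorrelation of the AR(p)-filtered series at MA iteration q. The
rendered 0/X table uses the flat 2/√N call. Vertex suggestion is more
careful: per-cell calls use Bartlett-scaled standard errors (a flat 2/√N
materially understates the variance of autocorrelations of serially
correlated series and produces spurious X's), the candidate vertex cell
itself is tested at the 1% level (one false call there invalidates the
whole search), and a candidate qualifies when at most 15% of the cells in
its asymptotic zero triangle are significant — the allowance for the ~5%
per-cell false-significance rate. The minimal (p+q, then p) qualifying cell
is returned; a table with no qualifying cell reports no clear vertex.
Series shorter than max(50, p_max+q_max+10) are refused.

## Mixed-effects growth model

The growth panel model for the ring index of tree j at site i in year k is

    I_ijk = (b₁+β₁ᵢ+β₁ᵢⱼ) + (b₂+β₂ᵢ+β₂ᵢⱼ)·A_ik + (b₃+β₃ᵢ+β₃ᵢⱼ)·D_ik + ε_ijk

with Gaussian random intercepts and slopes at the site and tree-within-site
levels, all mutually uncorrelated (diagonal covariance at each level,
enforced exactly), and a stationary AR(1) error with coefficient φ and
marginal SD σ within each tree. Across a gap of g missing years the error
correlation is φᵍ (the Markov-chain convention); gaps are logged, never
silently bridged by imputation.

Covariates enter in raw units — uncentered, unscaled. The annual GPP
covariate is carried on a scaled axis (annual mol m⁻² yr⁻¹ / 1000, so
values of ~0.04–0.12): on this axis the reference coefficient magnitudes
(intercept ≈ −0.32 mm, GPP slope ≈ 4.95, drought slope ≈ −1.5×10⁻⁴ per
code unit) are mutually consistent with near-zero mean indices, and the
drought slope's 10⁻⁴ scale matches raw drought-code units.

**Estimation.** REML. The restricted likelihood is evaluated exactly in
O(N): within each tree the stationary AR(1)/Markov correlation matrix has a
closed-form tridiagonal inverse (log-determinant `Σ log(1−ρ_m²)`), and the
two layers of rank-3 random effects are folded in by nested 3×3 Woodbury
identities per tree and per site. Fixed effects are profiled out by
generalized least squares at every evaluation. The optimizer is L-BFGS-B on
transformed parameters (log SDs, atanh φ, log σ; bounds keep |φ| < 0.9993)
with a moment-based start (OLS residual scale and pooled lag-1 residual
correlation) plus seeded perturbations as multiple starts (default 3) to
guard against local optima. Degenerate variance proposals are rejected by a
barrier value rather than crashing the line search. Boundary estimates
(SD → 0, e.g. a truly negligible tree-level drought slope) are flagged in
the fit report, not hidden.

Fixed-effect standard errors come from (XᵀV⁻¹X)⁻¹ at the optimum; p-values
use t statistics with containment-style degrees of freedom
(N − n_trees − 2), documented as approximate — estimates, not p-values, are
the quantities this package stands behind. AIC is `2k − 2·logREML` with
k = 11 (3 fixed + 6 RE SDs + φ + σ). BLUPs at both levels are the
empirical-Bayes conditional means `G·Zᵀ·V⁻¹·(y − Xβ̂)`; predictions are
population-level (Xβ̂) or BLUP-conditioned. Note that with a strongly
persistent AR(1) error the BLUP-conditioned per-tree residual means are
shrunken toward but not exactly zero — the persistent error component is
deliberately not absorbed into the random intercept.

Post-hoc analysis regresses the extracted BLUPs on covariates such as
relative height (Pearson correlation with two-sided p), mirroring the
two-stage practice of fitting first, then asking whether tree-level
responses track social status.

**Verification.** The Woodbury likelihood is checked against a dense
brute-force covariance construction to 8 decimals (including panels with
year gaps); the zero-variance, φ = 0 case reduces to the OLS restricted
likelihood analytically. Parameter recovery is checked at the full study
scale (44 sites × 14 trees × 81 years, one panel: every fixed effect within
2 estimated SEs of truth, φ within ±0.05) and in a 20-replicate calibration
at 8 × 4 × 30 scale (mean z within 3 Monte-Carlo SEs of zero; 95% interval
coverage in [85%, 100%]). Replicate counts and the reduced scale were
chosen to keep the suite's total runtime modest while leaving the
full-scale recovery itself exercised once.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed), with one named stream
per generator derived from the master seed by fixed offsets. Defaults
encode the study conditions: 44 sites × 14 subject trees over 1930–2010;
sinusoidal boreal temperature seasonality (amplitude 18 °C, site means
spanning −2..3 °C) with AR(1) daily noise; Bernoulli-gamma precipitation
calibrated once so the process-chain annual maximum drought codes span the
observed historical envelope (221.4–672.3); drought regressors drawn
uniform over that envelope (the 10⁻⁴-scale drought coefficient is only
identifiable against realistic regressor magnitudes); scaled GPP regressors
uniform on 0.04–0.12; mixed-model truth equal to the reference estimates,
with a residual marginal SD of 0.35 mm (not part of the reference table; a
typical residual-index spread). Stand structure uses lognormal DBH, a
power-law height allometry, and Poisson competitor plots whose pooled basal
areas fall in the surveyed 6–72 m² ha⁻¹ range.

Not emulated: spatial autocorrelation between sites, age-dependent index
variance, the climate-regressor cross-correlation structure of real sites
(regressors are drawn independently per site-year), disturbance pulses, and
episodes where the model systematically misfits (e.g. exceptional drought
decades). Passing recovery tests therefore demonstrates the estimator and
pipeline are correct and well-calibrated under the assumed data-generating
process — not that the scientific conclusions would survive violations of
those assumptions in field data.

## Degenerate inputs and tie-breaks

Constant series are rejected by ACF/CCF (undefined correlation); ESACF
refuses short series; duplicate site-days, duplicate (site, tree, year)
rows, inverted temperature extremes, negative precipitation/PAR/DBH/heights
and non-positive VPD all raise typed errors. Ties at the maximum height all
receive relative height 1. Zero-width rings are retained in series but
excluded from regional-curve means. The conductance floor (10⁻⁵) and the
γ ∈ [0, 1) range make the daily GPP computation total and non-negative.
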