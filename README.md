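# borealgrowth

Drought, photosynthetic production and competition effects on the radial
growth of boreal white spruce (*Picea glauca*) — a tested, reusable analysis
pipeline for forest ecophysiologists and dendroclimatologists working in
western Canadian mixedwood stands, and for anyone who needs its statistical
core: a two-level mixed-effects growth model with AR(1) errors fit by REML.

## What it computes

From daily climate records, ring-width series and stand competition tables,
the pipeline derives:

1. **Climate drivers** — vapor pressure deficit (Tetens), growing degree-days
   (TSUM), PAR from solar geometry, and annual summaries (MAT, MAP).
2. **Canadian Drought Code** — the daily May–October deep-soil moisture
   rating and its annual maximum D, the model's drought driver
   (0 = recharged, 200 = high, ≥300 = extreme severity).
3. **Annual photosynthetic production** A — a daily canopy GPP model with
   temperature acclimation,
   `A(t) = g·C_a·α·γ/(g + α·γ)`, where γ = Q/(Q+δ) is the light response,
   α = α_max/(1+exp(−b(S−T_s))) the capacity sigmoid of the acclimated
   temperature S (dS/dt = (T_air−S)/τ), and
   g = max(10⁻⁵, α·γ·(√(C_a·10⁻⁶·λ/(1.6·D)) − 1)) the optimal stomatal
   conductance (λ = 3000 kPa), integrated to mol m⁻² yr⁻¹.
4. **RCS ring indices** — Tucson/.rwl I/O, cross-dating QC against the
   leave-one-out master chronology, regional curve standardization, and
   residual indices I = measured − expected (mm).
5. **Competition metrics** — pooled stand basal area by species class,
   `BA = π·Σ(DBH/2000)²/(0.001·n_plots)` m² ha⁻¹, and relative height (the
   social-status / asymmetric-competition proxy).
6. **Identification** — ACF, CCF and the ESACF table (Tsay–Tiao iterated
   autoregression) with zero-triangle vertex suggestion of ARMA orders.
7. **The growth model** — for tree j at site i in year k,

       I_ijk = (b₁+β₁ᵢ+β₁ᵢⱼ) + (b₂+β₂ᵢ+β₂ᵢⱼ)·A_ik + (b₃+β₃ᵢ+β₃ᵢⱼ)·D_ik + ε_ijk

   with uncorrelated random intercepts and slopes at the site and
   tree-within-site levels and stationary AR(1) errors (coefficient φ)
   within trees, estimated by REML with fixed effects profiled by GLS.
   BLUPs at both levels feed a post-hoc regression of tree-level random
   effects on relative height — the asymmetric-competition test.

A synthetic-data module generates every input the pipeline reads (daily
boreal climate, stand structure, growth panels drawn from the mixed model),
so the whole chain is exercisable and verifiable without field data.

## Worked example

Run the full pipeline on synthetic inputs (six stands kept small here;
the library-level default is the 44-stand study configuration):

```bash
borealgrowth --seed 3 --out demo --config demo.yaml run-all
```

with `demo.yaml`:

```yaml
synthetic: {n_sites: 6, trees_per_site: 4, year_start: 1981, year_end: 2010}
fit: {n_starts: 1}
```

prints:

```
Linear mixed-effects model fit by REML
  observations: 720   sites: 6   trees: 24
  log-restricted-likelihood: 56.82   AIC: -91.65
  AR(1) phi: 0.841892   residual SD: 0.375071
  Fixed effects:
    intercept     -0.447382  SE 0.181415  p 0.0139
    gpp            7.599944  SE 1.471587  p 0.0000
    drought       -0.000249  SE 0.000189  p 0.1892
  Random-effect SDs (site / tree):
    intercept      0.423128 / 0.082455
    gpp            3.110585 / 3.346898
    drought        0.000446 / 0.000119
```

Read this as: interannual growth rises with annual photosynthetic
production (positive GPP slope, ≈ 7.6 index-mm per scaled GPP unit on this
small 6-stand draw — within two standard errors of the generating 4.95) and
falls with drought (negative slope per code unit, not significant at this
panel size); site-level random-effect spreads rival the fixed effects, i.e.
stands differ in their response about as much as the average response
itself; φ ≈ 0.84 says growth anomalies carry over strongly from year to
year. The
output directory also holds the drought-code and GPP tables, ring indices
and chronology, the identification report (`identification.txt`), BLUP
tables, a `posthoc_correlations.csv` relating tree-level random effects to
relative height, and a `manifest.json` with a content hash of every output.

Stages compose individually too: `synth`, `climate-derive`, `drought-code`,
`gpp`, `detrend`, `identify`, `fit`, `posthoc` each read and write plain
delimited tables.

## Documentation

`docs/methods.md` describes the models, parameter conventions (including
the scaled GPP covariate axis and the per-mole-fraction conductance units),
numerical methods (tridiagonal AR(1) inverses, nested Woodbury REML,
multi-start L-BFGS-B), and the limits of what the synthetic-data tests
demonstrate.
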