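# Methods

This note describes the models and procedures implemented in
`baseline_ensemble`, the assumptions behind the synthetic jurisdiction
generator, the numerical choices made where the design was genuinely
open, and the limits of what the test suite can show about real data.

## The quantity under study

A jurisdictional deforestation emission baseline is

```
B = R x C        [tCO2e/yr]
```

where `R` is the projected business-as-usual deforestation rate (km²/yr)
and `C` the average forest carbon density in CO₂-equivalent (tCO₂e/km²).
Crediting standards permit many choices for both factors.  The package
enumerates a grid of permitted method combinations —

| parameter | levels |
|---|---|
| projection approach | `hist`, `linear`, `poly2`, `global`, `global_s`, `regional`, `regional_s` |
| forest dataset variant | three tree-cover-threshold variants of a 30 m product (span 2000–2021), a 500 m product (2001–2020), a 300 m product (1992–2020) |
| historical reference length | 5–15 years |
| starting year | every year for which the window fits the variant's span |
| carbon forest mask | the same five dataset variants |
| AGB source | two wall-to-wall products + one sparse-sampling product |
| BGB source | two wall-to-wall products + a regional root:shoot ratio of AGB |
| SOC source | two products |

— computes `B` for every jurisdiction × combination, and summarises (i)
relative variability, CV = 100·SD/mean of a jurisdiction's baselines,
(ii) hindcast accuracy, forecast error = |predicted − actual| / actual
against the window following the reference window, (iii) propagated
relative uncertainty, and (iv) random-forest variable importance of the
grid parameters.  At full study scale (all start years, five masks,
~2,800 jurisdictions) the grid has ~1.4 × 10⁹ cells; the package only
*counts* that grid and evaluates configurable subsets.

## Projection approaches

* **hist** — arithmetic mean rate over the reference window.  No
  model-based uncertainty is assigned: prediction intervals are derived
  from the time-function and driver models only, so `hist` combinations
  are flagged and excluded from uncertainty summaries rather than given a
  substitute value.
* **linear / poly2** — OLS polynomial of rate on year over the window.
  The projection is the mean of the fitted curve over the future window
  of the same length (not the endpoint), and the 90% interval is the
  prediction interval for that mean of *h* future observations,
  `t₀.₉₅,df · sqrt(c'Vc + σ²/h)` with `c` the mean future design row.
* **global / regional** — regression of the per-jurisdiction
  window-mean rate on up to 12 driver covariates, fitted over all
  screened jurisdictions (global) or within each of six regions.  The
  response is Box-Cox transformed; observations with externally
  studentized residual |t| > 3 in a preliminary full fit are removed in
  one pass; bidirectional stepwise search minimising AIC selects the
  retained drivers (at least one driver is always kept).  Predictions and
  90% prediction intervals are computed on the transformed scale and
  mapped back through the monotone Box-Cox inverse, which preserves
  endpoint ordering for every λ; out-of-image values saturate at 0 or
  +∞, and non-finite point predictions are marked invalid downstream.
* **global_s / regional_s** — multi-model ensembles: repetitions
  (300 at study scale, fewer in the desk configurations) of the above
  regression on driver subsets of size uniform on {3,…,11}, sampled
  without replacement.  The ensemble point is the mean of member
  back-transformed predictions; the interval is the 5th/95th percentile
  of the member spread.  Failed members are dropped and counted; more
  than 50% failures aborts the cell.

Numerical choices worth knowing:

* **Box-Cox λ** is the response-only maximum-likelihood estimate
  (`scipy.stats.boxcox`), not a regression profile likelihood.  This
  makes the transform a property of the (scope, variant, window) response
  sample, shared by the full model and every ensemble member on that
  sample, and is much cheaper.  Zero responses are handled by adding an
  offset of half the smallest positive response, recorded in the model
  and subtracted after back-transform (then floored at 0).
* **Ensemble members skip the nested stepwise pass** by default: the
  random-subset averaging is itself the selection mechanism, and a
  stepwise search inside each of 300 members multiplies cost for little
  benefit.  `member_stepwise: true` restores it.
* **Non-negativity screening**: combinations projecting a negative rate
  are excluded from all statistics (not clamped to zero), since such
  baselines would be rejected in practice; valid intervals are floored at
  zero.

## Carbon

`C = 3.67 × [0.47 × (AGB + w·BGB) + w_soc × SOC]` in Mg/ha, ×100 to
t/km².  The 0.47 stoichiometric factor applies to biomass pools only
(SOC is already carbon); 3.67 is the CO₂/C molar-mass ratio.  The
belowground pool decays over roughly a decade after clearing, which is
treated as committed emission with weight `w = min(1, horizon/10)`;
the default horizon of 10 years gives `w = 1`.  Whether soil carbon is
fully counted is likewise a knob (`soc_inclusion_weight`, default 1),
because accounting practice varies.  Ratio-type BGB is the combination's
AGB times a regional root:shoot ratio; its pool uncertainty combines the
AGB source's uncertainty with the ratio's own in quadrature.

Pool uncertainties come from the configured provider value or default to
33% when none is published.  Pool contributions combine as
`u = sqrt(Σ(cᵢuᵢ)²)/Σcᵢ`, and rate and carbon uncertainties combine as
`sqrt(u_R² + u_C²)` — summation in quadrature under an independence
assumption throughout.

## Synthetic jurisdiction generator

No geospatial data ships with the package; the generator reproduces the
statistical structure the analysis assumes, with known ground truth:

* **Latent process**: `log rate_t = a + β·x_t + ε_t` with `ε` AR(1)
  (φ = 0.5, innovation SD 0.3 by default).  The intercept is
  `log(0.005 × initial forest area)` — about half a percent of forest
  lost per year.  A lognormal AR(1) keeps rates positive; the real
  generative process is unknown and this is an explicit stand-in.
* **Drivers**: 12 standardised covariates named after the usual
  biophysical/socioeconomic predictors, with 4 carrying true nonzero
  effects by default.  They are independent across drivers unless
  `driver_common_factor_loading` is set, which makes them load on one
  latent factor — emulating the strong mutual correlation of real
  covariates.  A small random-walk drift (SD 0.05/yr) makes them vary
  slowly in time.
* **Observation model**: each of the five dataset variants sees
  `latent × bias × lognormal noise` over its own calendar span, with
  per-variant bias (looser tree-cover thresholds register more loss) and
  noise CV (coarser products are noisier).  The observed stock series
  then enforces the clipping rule: a year's loss cannot exceed the
  previous year's stock, and stocks never increase.  With
  `noise_area_scaling` the noise CV grows as `sqrt(ref_area/forest)`,
  the mechanism by which small jurisdictions end up with more variable
  baselines.  The covariance structure *among* variants of real products
  is unknown; multiplicative bias plus independent noise is an
  assumption.
* **Carbon sources**: per-jurisdiction true densities are lognormal
  around each source's global mean (between-jurisdiction CV 0.30).  The
  sparse source draws 1,000 equal-area cells (within-jurisdiction CV
  0.30) and reports the mean of a 5% sample without replacement, with
  uncertainty inflated by the sampling standard error.  Mask variants
  perturb jurisdiction means by a small lognormal factor (CV 0.03).
* **Subnational structure**: jurisdictions above 10,000 km² of forest
  get 3–8 children whose latent series partition the national series by
  a Dirichlet share vector; screening then applies the inclusion rules
  (≥1,000 km² forest for national units, replacement of large nationals
  by their children, ≥10% forest cover for subnational units).
* **Seeding**: every draw comes from a named stream (jurisdiction ×
  purpose × variant/source) hashed from one root seed, so regeneration
  is bit-identical and adding jurisdictions never perturbs existing
  ones.

What passing tests do **not** show about real data: the generator has no
spatial autocorrelation, no systematic regional carbon biases, no missing
years, and its driver–deforestation link is log-linear by construction —
so parameter-recovery results certify the estimation machinery, not the
adequacy of any of those assumptions for actual forest-change products.

## Metrics and statistics

Per-jurisdiction statistics are medians across method combinations;
distributions across jurisdictions are summarised by the median and the
central 90% range (5th–95th percentiles).  Hindcast records with zero
actual rate are excluded (counted, not given infinite error).  Level
comparisons use one-way ANOVA plus Tukey HSD on per-jurisdiction level
statistics, treating jurisdiction-level values as independent
observations within each level; with jurisdictions appearing in several
levels this overstates independence, which is why the package reports
the tests as descriptive rather than confirmatory.  The area–variability
relationship is the Pearson correlation of log forest area with overall
CV.  Its sign in synthetic runs depends on which variance component
dominates.  Within any single projection approach it is non-positive
when observation noise scales with 1/√area.  Across approaches, however,
a second mechanism acts: the driver regressions shrink predictions
toward the sample mean (jurisdiction size is not fully expressible
through the standardised drivers), so jurisdictions with rates far above
the mean see a large gap between their average-based and
regression-based baselines — and because CV is asymmetric in the ratio
of the outlying to the central methods, this inflates the CV of
large-rate (large-forest) jurisdictions more, pushing the pooled
correlation positive.  The dedicated directional test (low process
noise, equal variant biases, a single carbon combination) isolates the
observation-noise mechanism and reproduces the negative sign; the
full-grid correlation reported by the bundled study is the net of both
mechanisms.

## Variable importance

`n_models` random forests (study scale 100 × 200 trees × 900,000 rows;
desk scale smaller) are each fitted on a random row subsample without
replacement, and permutation importance per grid parameter is computed
on rows the model did not train on; means and standard errors are taken
across models and parameters ranked.  Parameters are ordinal-encoded:
permutation importance shuffles whole columns, so the encoding does not
affect the measure, and it is invariant to monotone rescaling of the
response.  Single-level parameters are dropped with a warning;
`min_samples_leaf = 5` regularises the trees.  `start_year` is excluded
from the predictor set by default and can be enabled in configuration.

## Desk-scale execution

The bundled configurations shrink the grid (three dataset variants, three
reference lengths, two start years, two carbon masks, 30-member
ensembles, 20–150 jurisdictions) so a full run takes seconds to minutes
on one core; the full study-scale grid remains expressible in the same
configuration schema.  Regional models require more jurisdictions per
region than driver parameters (+5); in very small runs those cells are
marked invalid with a reason rather than fitted badly.  Baselines are
written in chunks; all CSV outputs are timestamp-free and byte-stable
for a given config and seed.

## Known limitations

* The ANOVA/Tukey pooling is descriptive (see above); no
  mixed-model correction for repeated jurisdictions is attempted.
* Ensemble intervals are member-spread percentiles, which measure
  structural disagreement, not predictive coverage.
* `hist` carries no uncertainty by design, so uncertainty summaries
  cover only model-based combinations.
* The logistic time function sometimes permitted by standards is not
  implemented; no spatially explicit allocation of deforestation is
  attempted.
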