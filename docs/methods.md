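# Methods

## Survey structure and scenario construction

The unit of observation is a pooled site count: transect counts are
summed within a site (five 50×5 m transects per site in the
reference-style design, three 25×5 m in the target-style design), per
year and per response (total abundance, or one fish family; the TOTAL
response is the sum over families). Seven scenarios define the
model-fitting datasets: A (2003–2007), B (2007–2013), C (2007–2013,
downscaled), D (2007), E (2007, downscaled), F (2013, downscaled), G
(2013). Multi-year windows are aggregated per site by the across-year
mean of pooled counts, rounded half-up so the NB likelihood keeps an
integer response; the rounding rule is applied once, at the final
integerisation step. Whether pooling across transects should precede or
follow year averaging is not determined by the survey design; this
package pools first, then averages.

### Downscaling

Converting 50 m transect counts to 25 m equivalents works per site. The
average increase in cumulative abundance per added transect is estimated
by accumulating transects in random order; counting the first transect
as the step from zero area makes the cumulative sum telescope, so the
mean step increment of *any* ordering equals total/n — the randomised
estimator is exactly the mean transect count, and the implementation
preserves that identity bit-for-bit by integer accumulation (999
permutations by default, fixed seed; the analytic shortcut is always
computed alongside). Each transect count then becomes
`count − (average increase / length ratio)`, rounded half-up, with
negatives clamped to zero (the formula goes negative for below-average
transects, but counts cannot). The canonical length ratio is 2
(50 m / 25 m). No information is shared across sites.

## Predictors

Sites are mapped to the nearest node of a regular predictor lattice
under a planar equidistant-cylindrical projection (km, anchored at the
domain mean latitude); ties go to the lowest node id. Distances to
boundary polylines (coast, outer reef limit) are planar point-to-segment
minima under the same projection. Predictors are mean-centred over the
fitting sites; `coast`, `barrier`, `depth` and `SST_av` (and `rugosity`
where present) carry raw quadratic columns computed on the centred
scale — raw rather than orthogonal polynomials keep coefficients
interpretable, and centring removes most linear–quadratic collinearity.
Per-predictor calibration ranges (min/max of centred values over the
fitting sites) are stored with the centring constants.

When a model is transferred, the *reference* system's centring constants
are applied to the target's predictors: the fitted coefficients are only
meaningful in the reference's centred coordinates. This is a documented
modelling choice; centring the target with its own constants would
silently re-interpret every coefficient. Target cells where any
predictor used by the model leaves the reference calibration range are
clipped — they carry no prediction, and all grid comparisons are
restricted to cells unclipped in both grids.

## Estimation

NB2 (variance μ + μ²/θ) with log link throughout. The GLM alternates
IRLS for β at fixed θ (statsmodels GLM with the NB family) with a
bounded scalar maximisation of the profile likelihood in log θ, until
the relative log-likelihood change falls below 1e-10 (at most 200
alternations); θ starts at a method-of-moments value from a Poisson fit
and β at the Poisson coefficients. θ counts as one estimated parameter.

The mixed model adds one Gaussian reef intercept, integrated out by a
Laplace approximation: per-reef conditional modes by damped Newton
(the conditional log-density is concave in the intercept; steps are
clipped at ±5), then the marginal log-likelihood as mode value plus
half-log-curvature correction. The outer optimisation is L-BFGS-B over
(β, log θ, log σ) with warm-started modes; σ² starts at 0.1. A fit with
σ below 1e-4 is reported as a boundary fit (σ²=0), not an error; at the
boundary the Laplace log-likelihood equals the GLM log-likelihood, which
the tests verify to 1e-6. σ² counts as one parameter in k. Coefficient
standard errors come from the conditional Fisher information X'WX at the
fitted modes; uncertainty in θ and σ is not propagated, matching common
mixed-model practice. One scalar random effect per group keeps Laplace
adequate at the group sizes simulated here; adaptive quadrature is not
implemented.

Predictions are population-mode by default (exp(Xβ), delta-method SE on
the response scale); conditional mode adds a group's fitted intercept
when the group was seen, else falls back to population. Grids of new
reefs therefore always use population mode.

The overdispersion that motivates NB2 is checked with a Pearson
dispersion statistic (Σ Pearson residual² / residual df) from a Poisson
GLM test fit.

## Model set and multimodel inference

Twelve fixed candidate models (full; boundary distances; physical;
three single-sediment; nutrients; oxygen/salinity; productivity;
temperature; light; intercept-only null), with system-specific
omissions: the target-style (NR) edition drops nitrate from the full
model and carbonates from the sediment model, and an optional edition
appends a quadratic-rugosity model 13. Ranking is by wAICc; ties break
to smaller k, then lower model id. "Top models" are those inside the top
0.9 cumulative weight. Effect sizes are wAICc-weighted means of
|coefficient × design-column SD| across the models *containing* the
predictor (absence is exclusion, not a zero); quadratic terms are
standardised by the SD of the squared centred column. The exact recipe
behind published "effect size" columns is not recoverable from text
sources, so this interpretation is stated openly. Model-averaged
predictions are wAICc-weighted means of response-scale predictions.

R²m/R²c for mixed models follow the variance-partitioning convention for
log-link NB models: R²m = σ²_f/(σ²_f+σ²_α+σ²_d),
R²c = (σ²_f+σ²_α)/(σ²_f+σ²_α+σ²_d), with σ²_f the variance of the
fixed-effects linear predictor over fitting sites and σ²_d the
lognormal-approximation distribution variance ln(1 + 1/λ + 1/θ), λ the
observed mean count; a trigamma variant ψ₁((1/λ+1/θ)⁻¹) sits behind a
switch. Fixed-effects models report 100×(1 − residual/null deviance),
both deviances evaluated at the fitted θ.

## Validation

Cross-validation is site-level k-fold (k=10 by default), stratified by
reef via shuffled round-robin so folds are balanced and every reef is
spread across folds where its size allows. Per fold the model is refitted
and held-out sites predicted in population mode; the error is the mean
absolute difference, aggregated as mean ± SD over folds, with a
percentage form dividing by the test fold's mean observed count (the
denominator convention is a documented choice). Direct validation is OLS
of observed on predicted counts, reporting 100×R² and the slope's
two-sided p.

Moran's I correlograms use binary weights over equal-width distance
bands; the default width is the first decile of the pairwise distance
distribution (a neighbourhood definition must be supplied somehow, and
this adapts to the survey's spatial grain). Inference is normality-based
(E[I] = −1/(n−1), the standard variance formula). Raw-scale response
residuals feed the correlograms in the pipeline.

## Transferability metrics

Four metrics compare a transferred grid with the target's own reference
grid over jointly unclipped cells: (ii) mean ± SD absolute difference,
with a percentage form whose denominator is the *reference* prediction
(the comparison is against the reference model, so the reference scales
it); (iii) percent of cells with relative difference ≤ 0.15,
boundary-inclusive, excluding zero-reference cells with the exclusion
count reported; (iv) percent high-vs-low agreement after min–max
rescaling the transferred grid onto the reference range, classes split
at each grid's own median with ties counted low (a midrange rule is
available — published usage never pins the classing rule down). Metric
(i) is direct validation of transferred predictions against target
observations. Identity transfer (a model against its own grid) is a
fixed point: zero difference, 100% within tolerance, 100% agreement —
verified in tests. Degenerate cases (constant grids, all cells clipped,
constant predictions) are routed into report notes rather than raised
mid-pipeline.

## Synthetic data

The generator emulates: reefs scattered uniformly in a lon/lat box with
Gaussian site clusters (SD 0.02°) around each reef centroid; smooth
covariate surfaces (linear lon/lat gradient plus low-frequency
sinusoids, rescaled into per-predictor ranges); a log-link linear
predictor over range-centred covariates (each linear column spans
[−1, 1], so coefficients are directly comparable across predictors);
reef intercepts Normal(0, σ_α²); NB2 site counts split across transects
by an equal-probability multinomial (within-site spatial structure is
not part of the generating model — the survey literature gives none —
so the split is exchangeable, and a configurable-probability variant
exists for stress tests). Family responses draw independent NB2 counts
with per-family mean shares and dispersions; TOTAL is their sum at
pooling time. All randomness descends from one integer seed through
named generators; the same seed reproduces tables byte-for-byte.

What the generator does *not* emulate: real species composition,
bathymetry, satellite-product noise, spatially correlated residuals
beyond the reef intercept, or observer effects. Passing tests therefore
demonstrate correctness of the algorithms and estimators under the
stated generative model, not ecological adequacy on real survey data.

Default study conditions used by the acceptance script: a reference
system of 15 reefs × 3 sites × 5 transects surveyed in six years
(2003–2013 odd years plus 2003/2005), and a target system of 10 reefs ×
3 sites × 3 shorter transects surveyed in 2013 with covariate ranges
shifted by 30% of their width; σ_α = 0.4, θ = 4, mean site abundance
300. These sizes mirror the reef/site/transect structure of long-term
reef monitoring at a scale where a full seven-scenario, three-response,
twelve-model study with 10-fold CV completes in about a minute.
Estimator-recovery checks run at 50 reefs × 20 sites, where the Laplace
approximation's bias is comfortably below sampling noise (median
relative bias of slope, σ_α and θ under 5% across replicates).

## Known limitations

- The Laplace likelihood can be mildly biased for σ_α at very small
  group counts or very low means; adaptive quadrature is out of scope.
- AICc treats the rounded multi-year mean counts as ordinary integer
  observations (no weights for the number of years averaged).
- Fold stratification by reef differs from an unstratified random fold
  scheme; with few sites per reef, some folds still lose whole reefs,
  in which case held-out predictions are population-mode (logged).
- Clipping is mandatory; the package never extrapolates outside the
  reference calibration range, so heavily shifted targets yield few or
  no comparable cells and the metric suite reports that rather than
  guessing.
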