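# reeftransfer

Tools for asking whether a statistical model of reef-fish abundance
fitted in one reef system can predict abundance in another.

Underwater visual censuses count fish along fixed-area belt transects at
sites nested within reefs. From such counts, `reeftransfer` builds the
seven canonical model-fitting datasets (year windows A–G, with an
optional transect-downscaling step that converts 50 m transect counts to
25 m equivalents), fits a fixed candidate set of twelve negative-binomial
count models with a reef-level random intercept, ranks them by
small-sample Akaike weights, and then quantifies *transferability*: how
well the model calibrated in a reference system predicts a target system
it has never seen.

## The model

Site-level pooled counts are modelled as NB2 with a log link:

    N_i ~ NegBin(mu_i, theta),      Var(N_i) = mu_i + mu_i^2 / theta
    log mu_i = x_i' beta + alpha_reef(i),   alpha_reef ~ Normal(0, sigma_alpha^2)

The reef random intercept absorbs the pseudo-replication of sites
sharing one 0.01° environmental grid cell; it is integrated out by a
Laplace approximation. Candidate models are ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and its weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); mixed models report marginal and
conditional R² (with the lognormal distribution-specific variance
ln(1 + 1/λ + 1/θ)), fixed-effects models report percent deviance
explained. A transferred model is evaluated by (i) validation R² against
target observations, (ii) mean absolute grid-cell difference from the
target's own reference predictions, (iii) the percentage of cells within
a 15% relative tolerance, and (iv) high-vs-low pattern agreement after
min–max rescaling — always with target cells clipped where any predictor
leaves the reference calibration range.

A synthetic twin-system generator with known coefficients, dispersion and
reef variance makes the whole pipeline testable end to end.

## Worked example

The library surface is sklearn-style estimators plus functional pipeline
stages:

```python
import numpy as np, pandas as pd
from reeftransfer import NegativeBinomialGLMM

rng = np.random.default_rng(7)
x = rng.normal(size=1000)
reefs = np.repeat(np.arange(50), 20)
mu = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.5, 50)[reefs])
y = rng.negative_binomial(5.0, 5.0 / (5.0 + mu))

fit = NegativeBinomialGLMM().fit(pd.DataFrame({"x": x}), y, groups=reefs)
print(fit.coef_, fit.theta_, np.sqrt(fit.sigma_alpha2_))
```

prints `[0.916 0.48 ] 4.684 0.523` — the intercept and slope, dispersion
and reef-SD recovered close to the generating values (1.0, 0.5, 5.0, 0.5).

A full run is driven from a YAML config (see `reeftransfer simulate --help`
and friends: `simulate`, `prepare`, `fit`, `validate`, `transfer`,
`report`). On a small synthetic twin-system config, `reeftransfer fit`
prints per-scenario rankings such as

```
scenario_id response  top_model    wAICc      R2m      R2c  cv_error_pct  first_lag_I
          D    TOTAL          3 0.336877 0.601664 0.601675     37.513113     0.311028
          G    TOTAL          6 0.423935 0.408329 0.581535     46.916267    -0.206281
```

(top model by Akaike weight, marginal/conditional R², 10-fold CV
percentage error, and first-lag Moran's I of the residuals), and
`reeftransfer transfer` prints the four transfer metrics per scenario:

```
scenario_id  val_R2_pct  abs_diff_mean  pct_cells_within_tol  pct_high_vs_low  n_cells
          D   52.631212     227.818402              1.886792        54.716981       53
          G   74.108247     261.435308              9.756098        51.219512       41
```

Here the target system shares the reference's generating coefficients, so
transferred predictions validate positively against target observations
(R² 53–74%), yet cell-level agreement with the target's own model stays
low — the clipped grid (53 of 121 cells survive a 30%-of-range covariate
shift) and reef-level noise dominate.

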