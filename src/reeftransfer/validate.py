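"""Model validation: cross-validation, observed-vs-predicted regression,
and spatial autocorrelation diagnostics.

Cross-validation partitions *sites* into k folds, stratified by reef so
every training set keeps every reef represented where possible (the
random-intercept design stays estimable).  Prediction error is the mean
absolute difference between held-out observed and predicted counts, also
expressed as a percentage of the fold's mean observed count.  Direct
validation regresses observed counts on model predictions and reports
R2 (as a percentage) and the slope's two-sided p-value.  Residual spatial
structure is summarised by a binary-weight Moran's I correlogram over
equal-width distance bands with normality-based z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .covariates import project_equidistant

__all__ = ["CVResult", "kfold_cv", "direct_validation", "moran_correlogram"]

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-fold and aggregate prediction errors of one model."""

    fold_errors: np.ndarray        # mean |obs - pred| per fold (counts)
    fold_pct_errors: np.ndarray    # 100 * fold error / fold mean observed
    fold_assignment: pd.Series     # site index -> fold id
    seed: int
    events: list[str] = field(default_factory=list)

    @property
    def error(self) -> float:
        return float(np.mean(self.fold_errors))

    @property
    def error_sd(self) -> float:
        return float(np.std(self.fold_errors, ddof=1))

    @property
    def pct_error(self) -> float:
        return float(np.mean(self.fold_pct_errors))

    @property
    def pct_error_sd(self) -> float:
        return float(np.std(self.fold_pct_errors, ddof=1))

    def summary(self) -> str:
        return (f"CV error {self.error:.1f} ± {self.error_sd:.1f} "
                f"({self.pct_error:.1f} ± {self.pct_error_sd:.1f}%)")


def _stratified_folds(groups: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold assignment within each reef after shuffling, so
    folds are balanced and each reef is spread across folds."""
    folds = np.empty(len(groups), dtype=int)
    offset = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger so small reefs don't all land in fold 0
    return folds


def kfold_cv(X: pd.DataFrame, y, groups, estimator, k: int = 10,
             seed: int = 0) -> CVResult:
    """k-fold site-level cross-validation of one model.

    ``estimator`` is an unfitted sklearn-style NB estimator; it is cloned
    and refitted per fold and held-out sites are predicted in population
    mode.  When a fold removes every site of a reef from training, the
    held-out prediction silently falls back to the population level (it
    already is population mode); the event is recorded.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available sites")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(groups, k, rng)
    errors, pct_errors, events = [], [], []
    accepts_groups = hasattr(estimator, "sigma2_start")  # mixed model
    for f in range(k):
        test = folds == f
        train = ~test
        est = clone(estimator)
        if accepts_groups:
            lost = set(groups[test]) - set(groups[train])
            if lost:
                events.append(f"fold {f}: reefs {sorted(map(str, lost))} absent from training")
            est.fit(X[train], y[train], groups=groups[train])
        else:
            est.fit(X[train], y[train])
        pred = est.predict(X[test])
        err = float(np.mean(np.abs(y[test] - pred)))
        errors.append(err)
        mean_obs = float(np.mean(y[test]))
        pct_errors.append(100.0 * err / mean_obs if mean_obs > 0 else np.nan)
    for e in events:
        log.info(e)
    return CVResult(np.asarray(errors), np.asarray(pct_errors),
                    pd.Series(folds, index=pd.RangeIndex(len(y)), name="fold"),
                    seed, events)


def direct_validation(observed, predicted) -> tuple[float, float]:
    """R2 (percent) and p-value of regressing observed on predicted counts.

    Ordinary least squares of observed against predicted; the p-value is
    the two-sided test of zero slope (equivalent to the regression F-test
    with one predictor).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted differ in length")
    if len(observed) < 3:
        raise ValueError("direct validation needs at least 3 pairs")
    if np.ptp(predicted) == 0:
        raise ValueError("constant predictions: validation regression undefined")
    res = stats.linregress(predicted, observed)
    return 100.0 * res.rvalue**2, float(res.pvalue)


def moran_correlogram(residuals, lon, lat, band_width_km: float | None = None,
                      n_bands: int = 10) -> pd.DataFrame:
    """Moran's I per distance band with normality-based inference.

    Weights are binary: w_ij = 1 when the planar (equidistant cylindrical)
    distance between sites i and j falls in the band.  Per band,
    I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    residuals; the expectation is -1/(n-1) and the variance is the
    standard normality formula.  The default band width is the first
    decile of the pairwise-distance distribution.  Empty bands are
    skipped with a note in the ``note`` column of the surviving rows'
    attrs.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran correlogram needs at least 4 sites")
    z = z - z.mean()
    denom = float(np.sum(z**2))
    if denom <= 0:
        raise ValueError("zero residual variance")
    x, y = project_equidistant(lon, lat, float(np.mean(lat)))
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    pair_d = d[iu]
    if band_width_km is None:
        band_width_km = float(np.quantile(pair_d, 0.10))
        if band_width_km <= 0:
            band_width_km = float(np.quantile(pair_d[pair_d > 0], 0.10))
    rows, skipped = [], []
    e_i = -1.0 / (n - 1)
    for b in range(n_bands):
        lo, hi = b * band_width_km, (b + 1) * band_width_km
        W_mat = ((d > lo) if b else (d >= lo)) & (d <= hi)
        np.fill_diagonal(W_mat, False)
        w = W_mat.astype(float)
        W = w.sum()
        if W == 0:
            skipped.append(b)
            continue
        num = float(z @ w @ z)
        I = (n / W) * num / denom
        s1 = 2.0 * W  # symmetric binary weights: S1 = sum (w_ij + w_ji)^2 / 2
        row_sums = w.sum(axis=1)
        s2 = float(np.sum((2.0 * row_sums) ** 2))
        var = ((n**2 * s1 - n * s2 + 3.0 * W**2)
               / (W**2 * (n**2 - 1.0))) - e_i**2
        var = max(var, 1e-300)
        zscore = (I - e_i) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zscore))
        rows.append({"band": b, "d_min_km": lo, "d_max_km": hi, "n_pairs": int(W / 2),
                     "I": I, "expected": e_i, "variance": var, "z": zscore, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["band_width_km"] = band_width_km
    out.attrs["skipped_bands"] = skipped
    return out


def correlogram_summary(correlogram: pd.DataFrame) -> str:
    """One-line plain-text summary naming the first-lag I and p."""
    first = correlogram.iloc[0]
    return (f"first-lag Moran's I = {first['I']:.3f} "
            f"(band 0-{first['d_max_km']:.1f} km, p = {first['p']:.3g})")
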