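"""Multimodel inference over the fixed candidate set.

Twelve models relate abundance to spatial and environmental predictors:
a full model, distances to domain boundaries, physical structure,
three single-sediment models, nutrients, oxygen/salinity, productivity,
temperature, light, and an intercept-only null; a thirteenth adds a
quadratic rugosity term where rugosity was measured.  Distances to coast
and barrier, depth and SST carry quadratic terms.  Models are ranked by
small-sample-corrected Akaike weights (wAICc); mixed models report
marginal/conditional R2 and fixed-effects models percent deviance
explained; per-predictor effect sizes are wAICc-weighted magnitudes of
standardised coefficients; predictions can be model-averaged across the
whole set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .nb import NegativeBinomialGLM, NegativeBinomialGLMM

__all__ = [
    "ModelSpec",
    "MODEL_SETS",
    "model_set",
    "aicc",
    "waicc_rank",
    "r2_nakagawa",
    "deviance_explained",
    "effect_sizes",
    "model_average_predictions",
    "fit_model_set",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a term list over PredictorSet columns."""

    model_id: int
    terms: tuple[str, ...]
    random_intercept: str | None = "reef"
    label: str = ""

    def design(self, pset_data: pd.DataFrame) -> pd.DataFrame:
        missing = [t for t in self.terms if t not in pset_data.columns]
        if missing:
            raise KeyError(f"model {self.model_id}: predictors missing from design: {missing}")
        # empty term list -> intercept-only null model
        return pset_data[list(self.terms)]


def _expand(*names: str, quadratic=("coast", "barrier", "depth", "SST_av", "rugosity")):
    terms: list[str] = []
    for n in names:
        terms.append(n)
        if n in quadratic:
            terms.append(n + "2")
    return tuple(terms)


def _build_set(edition: str) -> dict[int, tuple[str, ...]]:
    gbr = edition == "GBR"
    models = {
        1: _expand("coast", "barrier", "slope", *(["NO3_av"] if gbr else [])),
        2: _expand("coast", "barrier"),
        3: _expand("depth", "slope"),
        4: _expand(*(["crbnt", "gravel"] if gbr else ["gravel"])),
        5: _expand("sand"),
        6: _expand("mud"),
        7: _expand("NO3_av", "PO4_av", "SI_av"),
        8: _expand("O2_av", "Sal_av"),
        9: _expand("Chla_av"),
        10: _expand("SST_av"),
        11: _expand("K490_av"),
        12: (),
    }
    if edition == "NR+rugosity":
        models[13] = _expand("rugosity")
    return models


_LABELS = {
    1: "Full model", 2: "Distance to domain boundaries", 3: "Physical predictors",
    4: "Sediment characteristics", 5: "Sediment characteristics",
    6: "Sediment characteristics", 7: "Nutrients", 8: "Oxygen and salinity",
    9: "Productivity", 10: "Temperature", 11: "Light availability",
    12: "Null model", 13: "Rugosity",
}

#: Candidate sets per system edition.  The NR edition drops NO3 from the
#: full model and carbonates from the sediment model (collinear there);
#: NR+rugosity appends the quadratic-rugosity model 13.
MODEL_SETS: Mapping[str, Mapping[int, ModelSpec]] = {
    edition: {
        mid: ModelSpec(mid, terms, label=_LABELS[mid])
        for mid, terms in _build_set(edition).items()
    }
    for edition in ("GBR", "NR", "NR+rugosity")
}


def model_set(edition: str, random_intercept: str | None = "reef") -> dict[int, ModelSpec]:
    """The candidate set for one edition, with the random intercept toggled."""
    if edition not in MODEL_SETS:
        raise KeyError(f"unknown model-set edition {edition!r}")
    return {
        mid: ModelSpec(mid, spec.terms, random_intercept, spec.label)
        for mid, spec in MODEL_SETS[edition].items()
    }


def aicc(fit_or_loglik, k: int | None = None, n: int | None = None) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if k is None:
        ll, k, n = fit_or_loglik.loglik_, fit_or_loglik.k_, fit_or_loglik.n_
    else:
        ll = float(fit_or_loglik)
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def waicc_rank(fits: Mapping[int, object]) -> pd.DataFrame:
    """Rank a fitted candidate set by Akaike weight.

    Returns a DataFrame indexed by model_id, sorted best-first, with AICc,
    delta AICc, wAICc, and per-model fit summaries (R2m/R2c for mixed
    models, DE% otherwise).  All fits must share the response vector.
    Ties in weight go to the smaller parameter count, then lower model_id.
    """
    if not fits:
        raise ValueError("empty model set")
    ids = list(fits)
    ref_y = np.asarray(fits[ids[0]].y_)
    rows = []
    for mid in ids:
        f = fits[mid]
        if len(f.y_) != len(ref_y) or not np.array_equal(np.asarray(f.y_), ref_y):
            raise ValueError(f"model {mid} was fitted to a different response vector")
        a = aicc(f)
        row = {"model_id": mid, "k": f.k_, "loglik": f.loglik_, "AICc": a}
        if getattr(f, "sigma_alpha2_", None) is not None:
            row["R2m"], row["R2c"] = r2_nakagawa(f)
            row["DE_pct"] = np.nan
        else:
            row["R2m"] = row["R2c"] = np.nan
            row["DE_pct"] = deviance_explained(f)
        rows.append(row)
    tab = pd.DataFrame(rows).set_index("model_id")
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    w = np.exp(-0.5 * tab["dAICc"])
    tab["wAICc"] = w / w.sum()
    tab["_mid"] = tab.index
    tab = tab.sort_values(["dAICc", "k", "_mid"], kind="mergesort").drop(columns="_mid")
    return tab


def top_models(ranked: pd.DataFrame, cum_weight: float = 0.9) -> list[int]:
    """Models within the top cumulative weight (always at least the best)."""
    csum = ranked["wAICc"].cumsum()
    keep = ranked.index[(csum.shift(fill_value=0.0) < cum_weight)]
    return list(keep)


def r2_nakagawa(fit, variant: str = "lognormal") -> tuple[float, float]:
    """Marginal and conditional R2 for an NB log-link mixed model.

    R2m = var_f / (var_f + var_alpha + var_d); R2c adds var_alpha to the
    numerator.  var_f is the variance of the fixed-effects linear
    predictor over the fitting sites; var_d is the distribution-specific
    variance — the lognormal approximation ln(1 + 1/lambda + 1/theta) with
    lambda the observed mean count, or the trigamma form
    psi1((1/lambda + 1/theta)^-1) behind the ``variant`` switch.
    """
    eta_fix = np.log(np.maximum(fit.fitted_, 1e-300))
    if getattr(fit, "ranef_", None):
        codes = fit._codes_
        b = np.array([fit.ranef_[g] for g in fit.group_levels_])
        eta_fix = eta_fix - b[codes]
    var_f = float(np.var(eta_fix))
    var_a = float(fit.sigma_alpha2_ or 0.0)
    lam = float(np.mean(fit.y_))
    if lam <= 0:
        raise ValueError("zero mean count: distribution variance undefined")
    if variant == "lognormal":
        var_d = float(np.log1p(1.0 / lam + 1.0 / fit.theta_))
    elif variant == "trigamma":
        var_d = float(special.polygamma(1, 1.0 / (1.0 / lam + 1.0 / fit.theta_)))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    total = var_f + var_a + var_d
    if total <= 0:
        raise ValueError("zero total variance")
    return var_f / total, (var_f + var_a) / total


def deviance_explained(fit) -> float:
    """Percent of null deviance explained by a fixed-effects fit."""
    if fit.null_deviance_ <= 0:
        raise ValueError("null deviance is zero; deviance explained undefined")
    return 100.0 * (1.0 - fit.deviance_ / fit.null_deviance_)


def effect_sizes(ranked: pd.DataFrame, fits: Mapping[int, object],
                 predictor_sd: Mapping[str, float]) -> pd.Series:
    """wAICc-weighted mean |standardised coefficient| per predictor.

    A predictor's standardised coefficient in one model is coef times the
    SD of its design column; the mean is taken over the models *containing*
    the predictor with weights renormalised over those models (absence is
    exclusion, not zero).  Sorted descending, so ``.index[0]`` is the
    highest-effect predictor.
    """
    acc: dict[str, list[tuple[float, float]]] = {}
    for mid, f in fits.items():
        w = float(ranked.loc[mid, "wAICc"])
        for name, coef in zip(f.term_names_, f.coef_):
            if name == "Intercept":
                continue
            sd = predictor_sd.get(name)
            if sd is None:
                continue
            acc.setdefault(name, []).append((w, abs(coef) * sd))
    out = {}
    for name, pairs in acc.items():
        wsum = sum(w for w, _ in pairs)
        out[name] = (sum(w * e for w, e in pairs) / wsum) if wsum > 0 else 0.0
    if not out:
        return pd.Series(dtype=float)
    return pd.Series(out).sort_values(ascending=False)


def model_average_predictions(ranked: pd.DataFrame, fits: Mapping[int, object],
                              X: pd.DataFrame) -> np.ndarray:
    """wAICc-weighted mean of per-model response-scale predictions."""
    preds, weights, failures = [], [], []
    for mid, f in fits.items():
        try:
            preds.append(f.predict(X[list(f.term_names_[1:])]))
        except KeyError as exc:
            failures.append((mid, str(exc)))
            continue
        weights.append(float(ranked.loc[mid, "wAICc"]))
    if failures:
        raise KeyError(f"models unresolvable on the new design: {failures}")
    P = np.column_stack(preds)
    w = np.asarray(weights)
    return P @ (w / w.sum())


def fit_model_set(pset_data: pd.DataFrame, y, specs: Mapping[int, ModelSpec],
                  groups=None) -> dict[int, object]:
    """Fit every candidate model to one response vector.

    Uses the mixed model when a spec declares a random intercept and a
    grouping vector is supplied, else the plain GLM.
    """
    fits: dict[int, object] = {}
    for mid, spec in specs.items():
        Xm = spec.design(pset_data)
        if spec.random_intercept and groups is not None:
            fits[mid] = NegativeBinomialGLMM().fit(Xm, y, groups=groups)
        else:
            fits[mid] = NegativeBinomialGLM().fit(Xm, y)
    return fits
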