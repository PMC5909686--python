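"""Cross-system model transfer and its four-part metric suite.

A model calibrated in a reference system is applied to the target
system's predictor grid, with the target predictors centred using the
*reference* centring constants and any grid cell clipped (no prediction)
where a predictor used by the model falls outside the reference
calibration range.  Transferred and reference prediction grids are then
compared by (i) direct validation against target observations, (ii) mean
absolute grid-cell difference (with a percentage form relative to the
reference), (iii) the percentage of cells differing by at most a small
relative tolerance (15% by default), and (iv) the percentage of cells
agreeing on a high-vs-low classification after min-max rescaling the
transferred grid onto the reference range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import PredictorSet
from .validate import direct_validation

__all__ = [
    "predict_grid_clipped",
    "grid_abs_difference",
    "pct_within_tolerance",
    "rescale_minmax",
    "high_low_agreement",
    "transfer_report",
    "TransferReport",
]

DEFAULT_TOLERANCE = 0.15


def predict_grid_clipped(fit, pset: PredictorSet, grid: pd.DataFrame,
                         provenance: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Population-mode predictions on a predictor grid, with clipping.

    ``pset`` must be the PredictorSet of the *fitting* (reference) sites:
    its centring constants are applied to the grid's raw predictor values
    and its calibration ranges decide the clip mask.  Clipped cells carry
    NaN predictions.  Returns a PredictionGrid frame (node_id, longitude,
    latitude, predicted, se, clipped [+ provenance columns]).
    """
    centred = pset.apply_to(grid)
    terms = list(fit.term_names_[1:])
    clipped = pset.out_of_range_mask(centred, terms) if terms else np.zeros(len(grid), bool)
    mu, se = fit.predict(centred[terms], return_se=True)
    mu, se = np.asarray(mu, float), np.asarray(se, float)
    mu[clipped] = np.nan
    se[clipped] = np.nan
    out = pd.DataFrame({
        "node_id": grid["node_id"].to_numpy(),
        "longitude": grid["longitude"].to_numpy(),
        "latitude": grid["latitude"].to_numpy(),
        "predicted": mu,
        "se": se,
        "clipped": clipped,
    })
    for key, val in (provenance or {}).items():
        out[key] = val
    return out


def _joint_cells(transferred: pd.DataFrame, reference: pd.DataFrame):
    """Align on node_id and keep cells unclipped in both grids."""
    t = transferred.set_index("node_id")
    r = reference.set_index("node_id")
    if not t.index.sort_values().equals(r.index.sort_values()):
        raise ValueError("transferred and reference grids cover different node sets")
    r = r.reindex(t.index)
    ok = ~(t["clipped"].to_numpy() | r["clipped"].to_numpy())
    return t["predicted"].to_numpy()[ok], r["predicted"].to_numpy()[ok]


def grid_abs_difference(transferred: pd.DataFrame, reference: pd.DataFrame):
    """Mean ± SD absolute per-cell difference, plus its percentage form.

    The percentage form divides each cell's absolute difference by the
    reference prediction.  Returns ((mean, sd), (pct_mean, pct_sd)).
    """
    t, r = _joint_cells(transferred, reference)
    if len(t) == 0:
        raise ValueError("no jointly unclipped grid cells to compare")
    diff = np.abs(t - r)
    pct = 100.0 * diff / r
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    psd = float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0
    return (float(diff.mean()), sd), (float(pct.mean()), psd)


def pct_within_tolerance(transferred: pd.DataFrame, reference: pd.DataFrame,
                         tolerance: float = DEFAULT_TOLERANCE):
    """Percent of jointly unclipped cells with |t - r| / r <= tolerance.

    Cells with a zero reference prediction are excluded; the number
    excluded is returned alongside the percentage.
    """
    t, r = _joint_cells(transferred, reference)
    usable = r > 0
    excluded = int((~usable).sum())
    if usable.sum() == 0:
        raise ValueError("no cells with positive reference predictions")
    within = np.abs(t[usable] - r[usable]) / r[usable] <= tolerance
    return 100.0 * float(within.mean()), excluded


def rescale_minmax(values, target_min: float, target_max: float) -> np.ndarray:
    """Affine map sending (min(values), max(values)) to (target_min, target_max)."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    if hi <= lo:
        raise ValueError("constant input: min-max rescale is degenerate")
    return target_min + (v - lo) * (target_max - target_min) / (hi - lo)


def high_low_agreement(transferred: pd.DataFrame, reference: pd.DataFrame,
                       threshold: str = "median") -> float:
    """Percent of cells whose high/low class matches between grids.

    The transferred grid is first min-max rescaled onto the reference
    range; each grid's cells are classified high when strictly above the
    grid's own threshold (median by default, midrange optionally), ties
    counting as low.
    """
    t, r = _joint_cells(transferred, reference)
    if len(t) == 0:
        raise ValueError("no jointly unclipped grid cells to compare")
    if np.ptp(r) == 0 or np.ptp(t) == 0:
        raise ValueError("constant prediction grid: high/low classes undefined")
    t = rescale_minmax(t, float(r.min()), float(r.max()))

    def classify(v: np.ndarray) -> np.ndarray:
        if threshold == "median":
            cut = np.median(v)
        elif threshold == "midrange":
            cut = (v.min() + v.max()) / 2.0
        else:
            raise ValueError(f"unknown threshold rule {threshold!r}")
        return v > cut

    return 100.0 * float(np.mean(classify(t) == classify(r)))


@dataclass
class TransferReport:
    """The four transferability metrics for one (scenario, response) pair."""

    scenario_id: str
    response: str
    val_r2: float | None           # percent, on target observations
    val_p: float | None
    abs_diff: tuple[float, float]  # mean, sd (counts)
    pct_diff: tuple[float, float]  # mean, sd (percent of reference)
    pct_within: float              # metric (iii), percent of cells
    pct_within_excluded: int
    high_low: float | None         # metric (iv), percent agreement
    n_cells: int
    notes: list[str]

    def to_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "response": self.response,
            "val_R2_pct": self.val_r2,
            "val_p": self.val_p,
            "abs_diff_mean": self.abs_diff[0],
            "abs_diff_sd": self.abs_diff[1],
            "pct_diff_mean": self.pct_diff[0],
            "pct_diff_sd": self.pct_diff[1],
            "pct_cells_within_tol": self.pct_within,
            "pct_high_vs_low": self.high_low,
            "n_cells": self.n_cells,
            "notes": "; ".join(self.notes),
        }


def transfer_report(transferred: pd.DataFrame, reference: pd.DataFrame,
                    observed=None, predicted_at_sites=None,
                    tolerance: float = DEFAULT_TOLERANCE,
                    scenario_id: str = "", response: str = "",
                    threshold: str = "median") -> TransferReport:
    """Assemble the four-metric comparison of two prediction grids.

    ``observed``/``predicted_at_sites`` (optional) are the target-system
    site observations and the transferred model's predictions at those
    sites, feeding metric (i); degenerate metrics are routed into the
    report's notes instead of raised.
    """
    notes: list[str] = []
    val_r2 = val_p = None
    if observed is not None and predicted_at_sites is not None:
        try:
            val_r2, val_p = direct_validation(observed, predicted_at_sites)
        except ValueError as exc:
            notes.append(f"direct validation undefined: {exc}")
    abs_diff, pct_diff = grid_abs_difference(transferred, reference)
    pct_within, excluded = pct_within_tolerance(transferred, reference, tolerance)
    if excluded:
        notes.append(f"{excluded} cells with zero reference prediction excluded")
    try:
        high_low = high_low_agreement(transferred, reference, threshold)
    except ValueError as exc:
        high_low = None
        notes.append(f"high/low agreement undefined: {exc}")
    t, _ = _joint_cells(transferred, reference)
    return TransferReport(scenario_id, response, val_r2, val_p, abs_diff, pct_diff,
                          pct_within, excluded, high_low, len(t), notes)
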