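"""End-to-end orchestration: simulate -> prepare -> fit -> validate ->
transfer -> report, from a single declarative config with provenance.

The pipeline is deterministic given the config (all randomness flows from
the config's seeds) and single-threaded.  Every output table is written
as CSV next to a JSON sidecar carrying the config hash, the seed and the
package version, so any artifact can be traced back to the run that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import build_predictor_set, nearest_node_assign
from .nb import NegativeBinomialGLM, NegativeBinomialGLMM
from .prep import SCENARIOS, build_scenario
from .selection import (
    effect_sizes,
    fit_model_set,
    model_average_predictions,
    model_set,
    top_models,
    waicc_rank,
)
from .simulate import SystemConfig, generate_system, make_target_system
from .transfer import predict_grid_clipped, transfer_report
from .validate import kfold_cv, moran_correlogram

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_reference", "run_transfer", "load_config"]


@dataclass
class RunConfig:
    """Declarative description of one full run (see ``load_config``)."""

    reference: SystemConfig
    target: SystemConfig
    scenarios: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")
    responses: tuple[str, ...] = ("TOTAL",)
    model_edition_reference: str = "GBR"
    model_edition_target: str = "NR"
    k_folds: int = 10
    cv_top_models_only: bool = True
    tolerance: float = 0.15
    seed: int = 0
    out_dir: Path = Path("runs")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "reference": self.reference.to_json(),
                "target": self.target.to_json(),
                "scenarios": list(self.scenarios),
                "responses": list(self.responses),
                "editions": [self.model_edition_reference, self.model_edition_target],
                "k_folds": self.k_folds,
                "tolerance": self.tolerance,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file with ``reference:`` and ``target:``
    SystemConfig blocks plus optional run-level keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def sysconf(block: Mapping[str, Any]) -> SystemConfig:
        block = dict(block)
        if "covariate_ranges" in block:
            block["covariate_ranges"] = {
                k: tuple(v) for k, v in block["covariate_ranges"].items()
            }
        if "beta" in block:
            block["beta"] = dict(block["beta"])
        return SystemConfig(**block)

    ref = sysconf(raw["reference"])
    tgt = sysconf(raw["target"])
    kw = {k: v for k, v in raw.items() if k not in ("reference", "target")}
    if "out_dir" in kw:
        kw["out_dir"] = Path(kw["out_dir"])
    for key in ("scenarios", "responses"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return RunConfig(reference=ref, target=tgt, **kw)


def _write(df: pd.DataFrame, path: Path, meta: Mapping[str, Any]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"version": __version__, **meta}, indent=2, default=str)
    )


def _site_table(survey: pd.DataFrame) -> pd.DataFrame:
    return (survey.groupby(["system_id", "reef_id", "site_id"], as_index=False)
            .agg(longitude=("longitude", "first"), latitude=("latitude", "first")))


def _prepare_system(sys_cfg: SystemConfig, scenarios, responses, seed):
    """Simulate one system and build its scenario datasets and predictors."""
    survey, grid, truth = generate_system(sys_cfg)
    sites = _site_table(survey)
    assignment = nearest_node_assign(sites, grid)
    predictors = [c for c in grid.columns if c not in ("node_id", "longitude", "latitude")]
    raw_at_sites = grid.set_index("node_id").loc[assignment.to_numpy(), predictors]
    raw_at_sites.index = sites["site_id"]
    pset = build_predictor_set(raw_at_sites.reset_index(drop=True), predictors)
    datasets = {}
    for sc in scenarios:
        spec = SCENARIOS[sc]
        try:
            per_response = {
                resp: build_scenario(survey, spec, family_filter=resp, seed=seed)
                for resp in responses
            }
        except ValueError as exc:
            log.warning("skipping scenario %s for %s: %s", sc, sys_cfg.system_id, exc)
            continue
        datasets[sc] = per_response
    return {
        "survey": survey, "grid": grid, "truth": truth, "sites": sites,
        "pset": pset, "raw_at_sites": raw_at_sites, "datasets": datasets,
    }


def _align_response(samples: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Order scenario rows like the canonical site table."""
    return (sites[["site_id", "reef_id", "longitude", "latitude"]]
            .merge(samples, on=["site_id", "reef_id"], how="inner"))


def run_reference(config: RunConfig, system: str = "reference") -> dict:
    """Fit, rank, validate and grid-predict every (scenario, response).

    Returns a dict of artifacts; tables are also written under
    ``config.out_dir`` with provenance sidecars.  Per-cell failures are
    collected into the summary rather than aborting the run.
    """
    sys_cfg = config.reference if system == "reference" else config.target
    edition = (config.model_edition_reference if system == "reference"
               else config.model_edition_target)
    scenarios = config.scenarios if system == "reference" else ("G",)
    random_intercept = "reef" if system == "reference" else None

    prep = _prepare_system(sys_cfg, scenarios, config.responses, config.seed)
    specs = model_set(edition, random_intercept)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "system": sys_cfg.system_id, "edition": edition}
    out_dir = Path(config.out_dir) / sys_cfg.system_id

    results: dict = {"prep": prep, "fits": {}, "rankings": {}, "cv": {},
                     "correlograms": {}, "grids": {}, "failures": []}
    rank_rows = []
    sd = prep["pset"].data.std(ddof=1).to_dict()
    for sc, per_resp in prep["datasets"].items():
        for resp, samples in per_resp.items():
            aligned = _align_response(samples, prep["sites"])
            y = aligned["pooled_count"].to_numpy()
            pset_data = prep["pset"].data.set_axis(prep["sites"]["site_id"]).loc[
                aligned["site_id"]].reset_index(drop=True)
            groups = aligned["reef_id"].to_numpy()
            try:
                fits = fit_model_set(pset_data, y, specs,
                                     groups=groups if random_intercept else None)
                ranked = waicc_rank(fits)
            except Exception as exc:  # keep going; report at the end
                results["failures"].append((sc, resp, repr(exc)))
                log.warning("scenario %s / %s failed: %s", sc, resp, exc)
                continue
            best = int(ranked.index[0])
            eff = effect_sizes(ranked, fits, sd)
            cv_ids = top_models(ranked) if config.cv_top_models_only else list(fits)
            cv = {}
            for mid in cv_ids:
                proto = (NegativeBinomialGLMM() if random_intercept
                         else NegativeBinomialGLM())
                Xm = specs[mid].design(pset_data)
                try:
                    cv[mid] = kfold_cv(Xm, y, groups, proto,
                                       k=min(config.k_folds, len(y)), seed=config.seed)
                except Exception as exc:
                    results["failures"].append((sc, resp, f"cv model {mid}: {exc!r}"))
            resid = y - fits[best].fitted_
            try:
                corr = moran_correlogram(resid, aligned["longitude"], aligned["latitude"])
            except ValueError as exc:
                corr = None
                results["failures"].append((sc, resp, f"correlogram: {exc!r}"))
            grid_pred = predict_grid_clipped(
                fits[best], prep["pset"], prep["grid"],
                provenance={"scenario_id": sc, "model_id": str(best),
                            "reference_system": sys_cfg.system_id},
            )
            avg_sites = model_average_predictions(ranked, fits, pset_data)

            results["fits"][(sc, resp)] = fits
            results["rankings"][(sc, resp)] = ranked
            results["cv"][(sc, resp)] = cv
            results["correlograms"][(sc, resp)] = corr
            results["grids"][(sc, resp)] = grid_pred
            results["avg_site_predictions", sc, resp] = avg_sites

            best_cv = cv.get(best)
            rank_rows.append({
                "scenario_id": sc, "response": resp, "top_model": best,
                "top_models_0.9w": ",".join(map(str, top_models(ranked))),
                "wAICc": float(ranked.loc[best, "wAICc"]),
                "R2m": float(ranked.loc[best, "R2m"]),
                "R2c": float(ranked.loc[best, "R2c"]),
                "DE_pct": float(ranked.loc[best, "DE_pct"]),
                "null_wAICc": float(ranked.loc[12, "wAICc"]),
                "highest_effect": eff.index[0] if len(eff) else "",
                "pred_min": float(np.nanmin(grid_pred["predicted"])),
                "pred_max": float(np.nanmax(grid_pred["predicted"])),
                "cv_error": best_cv.error if best_cv else np.nan,
                "cv_error_pct": best_cv.pct_error if best_cv else np.nan,
                "first_lag_I": float(corr.iloc[0]["I"]) if corr is not None else np.nan,
            })
            _write(ranked.reset_index(), out_dir / f"ranking_{sc}_{resp}.csv", meta)
            _write(grid_pred, out_dir / f"grid_{sc}_{resp}.csv", meta)

    summary = pd.DataFrame(rank_rows)
    results["summary"] = summary
    if not summary.empty:
        _write(summary, out_dir / "summary.csv", meta)
    return results


def run_transfer(config: RunConfig, reference_results: dict,
                 target_results: dict) -> pd.DataFrame:
    """Apply every reference (scenario, response) top model to the target
    grid and observations; returns the table of TransferReports."""
    ref_prep = reference_results["prep"]
    tgt_prep = target_results["prep"]
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    rows = []
    for (sc, resp), fits in reference_results["fits"].items():
        ranked = reference_results["rankings"][(sc, resp)]
        best = int(ranked.index[0])
        fit = fits[best]
        # target grid predicted in the reference's centred coordinates
        transferred = predict_grid_clipped(
            fit, ref_prep["pset"], tgt_prep["grid"],
            provenance={"scenario_id": sc, "model_id": str(best),
                        "reference_system": config.reference.system_id},
        )
        tgt_key = next(iter(target_results["grids"]))
        reference_grid = target_results["grids"][(tgt_key[0], resp)]
        # transferred predictions at the target's surveyed sites
        tgt_samples = target_results["prep"]["datasets"][tgt_key[0]][resp]
        aligned = _align_response(tgt_samples, tgt_prep["sites"])
        centred_sites = ref_prep["pset"].apply_to(
            tgt_prep["raw_at_sites"].reset_index(drop=True)
        ).set_axis(tgt_prep["sites"]["site_id"]).loc[aligned["site_id"]]
        terms = list(fit.term_names_[1:])
        site_mask = ref_prep["pset"].out_of_range_mask(centred_sites, terms) if terms \
            else np.zeros(len(centred_sites), bool)
        pred_sites = fit.predict(centred_sites[terms].reset_index(drop=True))
        obs = aligned["pooled_count"].to_numpy()[~site_mask]
        try:
            rep = transfer_report(
                transferred, reference_grid,
                observed=obs, predicted_at_sites=pred_sites[~site_mask],
                tolerance=config.tolerance, scenario_id=sc, response=resp,
            )
            rows.append(rep.to_row())
        except ValueError as exc:
            rows.append({"scenario_id": sc, "response": resp,
                         "notes": f"transfer degenerate: {exc}"})
    table = pd.DataFrame(rows)
    _write(table, Path(config.out_dir) / "transfer_reports.csv", meta)
    return table
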