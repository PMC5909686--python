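"""Synthetic twin reef systems with known generative parameters.

Emulates the sampling design of a long-term underwater-visual-census
program: reefs scattered over a planar degree grid, a few sites clustered
around each reef centroid, and a fixed number of belt transects per site.
Site-level expected abundance follows a log-link linear predictor over
smooth environmental gradients plus a reef-level random intercept; counts
are NB2 (variance mu + mu^2/theta) and are split across transects by an
equal-probability multinomial, so transect counts sum exactly to the site
draw.  Every quantity needed for parameter-recovery tests is returned in a
truth record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SystemConfig", "generate_system", "make_target_system"]

#: theta above this is treated as the Poisson limit when drawing counts
_POISSON_THETA = 1e8


@dataclass(frozen=True)
class SystemConfig:
    """Generative description of one reef system.

    Parameters
    ----------
    system_id : str
        Label carried through every output table.
    n_reefs, sites_per_reef, transects_per_site : int
        Survey design; the classic design is five transects per site and
        three sites per reef.
    transect_length_m : float
        50 for the reference-style system, 25 for the target-style one.
    years : sequence of int
        Survey years; counts are drawn independently per (site, year).
    beta : mapping predictor -> float
        Fixed effects on the log scale, keyed by predictor name, with
        "Intercept" for the intercept and ``<name>2`` for a quadratic term
        on the centred predictor.  Applied to range-centred, half-width
        scaled covariates (so each linear column lies in [-1, 1]).
    sigma_alpha : float
        SD of the reef random intercept (log scale).
    theta : float
        NB2 dispersion; variance = mu + mu^2/theta.
    covariate_ranges : mapping predictor -> (min, max)
        Range each covariate spans across the system.
    families : mapping family -> (share, theta), optional
        If given, per-family counts are drawn with mean ``share * mu`` and
        family-specific dispersion; otherwise a single TOTAL response is
        drawn.
    lon_range, lat_range : (min, max) degrees
        Bounding box reef centroids are placed in.
    site_scatter_deg : float
        SD of the Gaussian scatter of sites around their reef centroid.
    grid_step_deg : float
        Lattice spacing of the predictor grid (0.01-degree style).
    seed : int
        Single source of randomness for the whole system.
    """

    system_id: str
    n_reefs: int
    sites_per_reef: int
    transects_per_site: int = 5
    transect_length_m: float = 50.0
    years: Sequence[int] = (2013,)
    beta: Mapping[str, float] = field(default_factory=lambda: {"Intercept": np.log(50.0)})
    sigma_alpha: float = 0.0
    theta: float = 5.0
    covariate_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    families: Mapping[str, tuple[float, float]] | None = None
    lon_range: tuple[float, float] = (145.0, 147.0)
    lat_range: tuple[float, float] = (-19.0, -17.0)
    site_scatter_deg: float = 0.02
    grid_step_deg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reefs < 1:
            raise ValueError("n_reefs must be >= 1")
        if self.sites_per_reef < 1:
            raise ValueError("sites_per_reef must be >= 1")
        if self.transects_per_site < 1:
            raise ValueError("transects_per_site must be >= 1")
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")
        for name, (lo, hi) in self.covariate_ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"covariate range for {name!r} must be finite with min < max")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["beta"] = dict(self.beta)
        d["covariate_ranges"] = {k: list(v) for k, v in self.covariate_ranges.items()}
        if self.families is not None:
            d["families"] = {k: list(v) for k, v in self.families.items()}
        return json.dumps(d, indent=2, sort_keys=True)


def _covariate_field(name_idx, lon, lat, cfg, rng):
    """Smooth covariate surface: a linear lon/lat gradient plus low-frequency
    sinusoidal noise, mapped to [0, 1] before scaling into the target range."""
    lon0, lon1 = cfg.lon_range
    lat0, lat1 = cfg.lat_range
    u = (lon - lon0) / (lon1 - lon0)
    v = (lat - lat0) / (lat1 - lat0)
    # deterministic per-covariate orientation and phase, drawn once from rng
    w = rng.uniform(-1.0, 1.0, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    amp = 0.15
    raw = w[0] * u + w[1] * v + amp * (
        np.sin(2 * np.pi * u + phase[0]) + np.sin(2 * np.pi * v + phase[1])
    )
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:  # degenerate orientation; fall back to plain gradient
        raw = u + v
        lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


def _scaled_covariates(cfg: SystemConfig, lon: np.ndarray, lat: np.ndarray,
                       field_rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for i, (name, (lo, hi)) in enumerate(cfg.covariate_ranges.items()):
        unit = _covariate_field(i, lon, lat, cfg, field_rng)
        cols[name] = lo + unit * (hi - lo)
    return pd.DataFrame(cols)


def _centred(cfg: SystemConfig, cov: pd.DataFrame) -> pd.DataFrame:
    """Range-centred covariates: (x - mid) / half-width, in [-1, 1]."""
    out = {}
    for name, (lo, hi) in cfg.covariate_ranges.items():
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        out[name] = (cov[name] - mid) / half
    return pd.DataFrame(out)


def _linear_predictor(cfg: SystemConfig, centred: pd.DataFrame, n: int) -> np.ndarray:
    eta = np.zeros(n)
    for term, coef in cfg.beta.items():
        if term == "Intercept":
            eta = eta + coef
        elif term.endswith("2") and term[:-1] in centred.columns:
            eta = eta + coef * centred[term[:-1]].to_numpy() ** 2
        elif term in centred.columns:
            eta = eta + coef * centred[term].to_numpy()
        else:
            raise KeyError(f"beta names unknown predictor {term!r}")
    return eta


def _draw_nb2(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    if theta >= _POISSON_THETA:
        return rng.poisson(mu)
    return rng.negative_binomial(theta, theta / (theta + mu))


def generate_system(config: SystemConfig):
    """Simulate one reef system.

    Returns
    -------
    survey : pandas.DataFrame
        Long-format transect table with columns (system_id, reef_id,
        site_id, latitude, longitude, year, transect_id, family, count).
    grid : pandas.DataFrame
        Predictor lattice (node_id, longitude, latitude, covariates).
    truth : dict
        Generative truth: beta, sigma_alpha, theta, per-reef random
        intercepts, per-site mu, and the site-level covariate table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # independent streams so adding sites never perturbs the covariate fields
    field_rng = np.random.default_rng(rng.integers(2**31))
    layout_rng = np.random.default_rng(rng.integers(2**31))
    count_rng = np.random.default_rng(rng.integers(2**31))

    reef_lon = layout_rng.uniform(*cfg.lon_range, size=cfg.n_reefs)
    reef_lat = layout_rng.uniform(*cfg.lat_range, size=cfg.n_reefs)
    alpha = (layout_rng.normal(0.0, cfg.sigma_alpha, size=cfg.n_reefs)
             if cfg.sigma_alpha > 0 else np.zeros(cfg.n_reefs))

    n_sites = cfg.n_reefs * cfg.sites_per_reef
    reef_idx = np.repeat(np.arange(cfg.n_reefs), cfg.sites_per_reef)
    site_lon = reef_lon[reef_idx] + layout_rng.normal(0, cfg.site_scatter_deg, n_sites)
    site_lat = reef_lat[reef_idx] + layout_rng.normal(0, cfg.site_scatter_deg, n_sites)

    cov = _scaled_covariates(cfg, site_lon, site_lat, np.random.default_rng(cfg.seed + 1))
    centred = _centred(cfg, cov)
    eta = _linear_predictor(cfg, centred, n_sites) + alpha[reef_idx]
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        bad = int(np.argmax(~np.isfinite(mu)))
        worst = max(cfg.beta, key=lambda t: abs(cfg.beta[t]))
        raise FloatingPointError(
            f"non-finite expected count at site index {bad} "
            f"(eta={eta[bad]:.2f}); largest coefficient is {worst!r}={cfg.beta[worst]}"
        )

    fam_specs = cfg.families if cfg.families is not None else {"TOTAL": (1.0, cfg.theta)}

    rows = []
    site_mu = {}
    for s in range(n_sites):
        reef = reef_idx[s]
        reef_id = f"{cfg.system_id}-R{reef:03d}"
        site_id = f"{reef_id}-S{s % cfg.sites_per_reef:02d}"
        site_mu[site_id] = float(mu[s])
        for year in cfg.years:
            for fam, (share, fam_theta) in fam_specs.items():
                site_count = int(_draw_nb2(count_rng, np.array([share * mu[s]]), fam_theta)[0])
                split = count_rng.multinomial(
                    site_count, np.full(cfg.transects_per_site, 1.0 / cfg.transects_per_site)
                )
                for t in range(cfg.transects_per_site):
                    rows.append((cfg.system_id, reef_id, site_id, site_lat[s], site_lon[s],
                                 int(year), f"T{t + 1}", fam, int(split[t])))

    survey = pd.DataFrame(
        rows,
        columns=["system_id", "reef_id", "site_id", "latitude", "longitude",
                 "year", "transect_id", "family", "count"],
    )

    grid = _predictor_grid(cfg)

    truth = {
        "system_id": cfg.system_id,
        "beta": dict(cfg.beta),
        "sigma_alpha": cfg.sigma_alpha,
        "theta": cfg.theta,
        "alpha_by_reef": {f"{cfg.system_id}-R{r:03d}": float(alpha[r]) for r in range(cfg.n_reefs)},
        "mu_by_site": site_mu,
        "site_covariates": cov.assign(
            site_id=sorted(site_mu), longitude=site_lon, latitude=site_lat
        ),
        "centring": {
            name: ((lo + hi) / 2.0, (hi - lo) / 2.0)
            for name, (lo, hi) in cfg.covariate_ranges.items()
        },
    }
    # site ids in generation order, not sorted
    truth["site_covariates"]["site_id"] = [
        f"{cfg.system_id}-R{reef_idx[s]:03d}-S{s % cfg.sites_per_reef:02d}"
        for s in range(n_sites)
    ]
    return survey, grid, truth


def _predictor_grid(cfg: SystemConfig) -> pd.DataFrame:
    lons = np.arange(cfg.lon_range[0], cfg.lon_range[1] + cfg.grid_step_deg / 2, cfg.grid_step_deg)
    lats = np.arange(cfg.lat_range[0], cfg.lat_range[1] + cfg.grid_step_deg / 2, cfg.grid_step_deg)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    cov = _scaled_covariates(cfg, glon, glat, np.random.default_rng(cfg.seed + 1))
    grid = pd.DataFrame({"node_id": np.arange(glon.size), "longitude": glon, "latitude": glat})
    return pd.concat([grid, cov], axis=1)


def make_target_system(config: SystemConfig, range_shift: Mapping[str, float],
                       **overrides) -> SystemConfig:
    """Derive a target-system config with shifted covariate ranges.

    ``range_shift`` maps predictor name to an additive offset applied to
    both ends of its range, so a shift equal to the full range width
    produces zero overlap with the reference range and a shift of half the
    width leaves exactly 50% overlap.  Extra keyword overrides (system_id,
    seed, design sizes ...) are applied on top.
    """
    for name, off in range_shift.items():
        if not np.isfinite(off):
            raise ValueError(f"range shift for {name!r} must be finite")
        if name not in config.covariate_ranges:
            raise KeyError(f"range shift names unknown predictor {name!r}")
    new_ranges = {
        name: (lo + range_shift.get(name, 0.0), hi + range_shift.get(name, 0.0))
        for name, (lo, hi) in config.covariate_ranges.items()
    }
    return dataclasses.replace(config, covariate_ranges=new_ranges, **overrides)
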