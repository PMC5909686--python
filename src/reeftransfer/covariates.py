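"""Per-site predictor construction.

Sites are assigned to the nearest node of a regular 0.01-degree style
predictor lattice under a planar equidistant-cylindrical projection
(kilometres, anchored at the domain's mean latitude); spatial predictors
are shortest distances to boundary polylines (coastline, outer reef
limit); predictors are mean-centred over the fitting sites and selected
ones expanded with raw quadratic columns on the centred scale.  Centring
constants and per-predictor calibration ranges are retained so a model
fitted in one system can be applied to another in the *reference*
system's coordinates, with out-of-range cells clipped downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, shape

__all__ = [
    "EARTH_RADIUS_KM",
    "project_equidistant",
    "nearest_node_assign",
    "distance_to_boundary",
    "load_boundary_geojson",
    "PredictorSet",
    "build_predictor_set",
]

EARTH_RADIUS_KM = 6371.0


def project_equidistant(lon, lat, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equidistant cylindrical projection to kilometres, anchored at lat0."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.deg2rad(lon) * EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(lat) * EARTH_RADIUS_KM
    return x, y


def nearest_node_assign(sites: pd.DataFrame, grid: pd.DataFrame) -> pd.Series:
    """Map each site to its nearest grid node (planar km distance).

    Ties are broken by the lowest node_id.  Returns a Series of node_ids
    indexed like ``sites``.
    """
    if grid.empty:
        raise ValueError("predictor grid is empty")
    lat0 = float(grid["latitude"].mean())
    gx, gy = project_equidistant(grid["longitude"], grid["latitude"], lat0)
    sx, sy = project_equidistant(sites["longitude"], sites["latitude"], lat0)
    tree = cKDTree(np.column_stack([gx, gy]))
    pts = np.column_stack([sx, sy])
    dist, idx = tree.query(pts)
    node_ids = grid["node_id"].to_numpy()
    chosen = node_ids[idx].copy()
    # enforce the documented tie-break: among all nodes at the minimal
    # distance (within float slack), take the smallest node_id
    for i in range(len(pts)):
        near = tree.query_ball_point(pts[i], dist[i] * (1 + 1e-9) + 1e-9)
        if len(near) > 1:
            chosen[i] = node_ids[near].min()
    return pd.Series(chosen, index=sites.index, name="node_id")


def load_boundary_geojson(path) -> np.ndarray:
    """Read a GeoJSON LineString (or Feature wrapping one) as (lon, lat) vertices."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    geom = shape(obj)
    if not isinstance(geom, LineString):
        raise ValueError(f"expected a LineString boundary, got {geom.geom_type}")
    return np.asarray(geom.coords, dtype=float)


def distance_to_boundary(site_lonlat: Sequence[float], boundary: np.ndarray,
                         lat0: float | None = None) -> float:
    """Shortest distance (km) from a site to a boundary polyline.

    The polyline is an array of (lon, lat) vertices; distance is planar
    point-to-segment under the equidistant cylindrical projection anchored
    at ``lat0`` (defaults to the polyline's mean latitude).
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[0] < 2:
        raise ValueError("boundary polyline needs at least 2 vertices")
    if lat0 is None:
        lat0 = float(boundary[:, 1].mean())
    bx, by = project_equidistant(boundary[:, 0], boundary[:, 1], lat0)
    line = LineString(np.column_stack([bx, by]))
    if line.length == 0:
        raise ValueError("degenerate boundary polyline (zero length)")
    sx, sy = project_equidistant([site_lonlat[0]], [site_lonlat[1]], lat0)
    return float(Point(sx[0], sy[0]).distance(line))


@dataclass
class PredictorSet:
    """Design-ready predictors with their centring and calibration state.

    ``data`` holds centred linear columns and, for predictors listed in
    ``quadratic``, squared-centred columns named ``<name>2``.  ``centres``
    are the fitting-site means subtracted from each raw predictor;
    ``calibration_ranges`` are per-predictor (min, max) of the *centred*
    values over the fitting sites, used later for clipping transferred
    predictions.
    """

    data: pd.DataFrame
    centres: dict[str, float]
    quadratic: tuple[str, ...]
    calibration_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return list(self.centres)

    def apply_to(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Centre new raw predictor values with the stored constants and
        rebuild the quadratic columns.  Idempotent on already-centred data
        only if the stored centres are zero; callers pass raw values."""
        cols = {}
        for name, centre in self.centres.items():
            if name not in raw.columns:
                raise KeyError(f"predictor {name!r} missing from new data")
            cols[name] = raw[name].to_numpy(dtype=float) - centre
        for name in self.quadratic:
            cols[name + "2"] = cols[name] ** 2
        return pd.DataFrame(cols, index=raw.index)

    def out_of_range_mask(self, centred: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
        """True where any *linear* predictor behind ``terms`` falls outside
        its calibration range (quadratic terms defer to their base)."""
        bases = {t[:-1] if t.endswith("2") and t[:-1] in self.centres else t for t in terms}
        mask = np.zeros(len(centred), dtype=bool)
        for b in bases:
            lo, hi = self.calibration_ranges[b]
            v = centred[b].to_numpy()
            mask |= (v < lo) | (v > hi)
        return mask

    def to_json(self) -> str:
        return json.dumps(
            {
                "centres": self.centres,
                "quadratic": list(self.quadratic),
                "calibration_ranges": {k: list(v) for k, v in self.calibration_ranges.items()},
            },
            indent=2,
            sort_keys=True,
        )


#: predictors expanded to second-order polynomials in the canonical model set
DEFAULT_QUADRATIC = ("coast", "barrier", "depth", "SST_av")


def build_predictor_set(raw: pd.DataFrame, predictors: Sequence[str] | None = None,
                        quadratic: Sequence[str] | None = None) -> PredictorSet:
    """Centre predictors over the fitting sites and expand quadratics.

    Quadratic columns are raw squares of the centred values (not
    orthogonal polynomials), so coefficients stay interpretable; centring
    removes most linear-quadratic collinearity.  Raises on constant
    columns, which are uncentrable for calibration ranges and collinear
    with the intercept by construction.
    """
    if predictors is None:
        predictors = [c for c in raw.columns
                      if c not in ("node_id", "longitude", "latitude", "site_id")]
    quadratic = tuple(q for q in (quadratic if quadratic is not None else DEFAULT_QUADRATIC)
                      if q in predictors)
    centres, cols, ranges = {}, {}, {}
    for name in predictors:
        v = raw[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"predictor {name!r} is constant over the fitting sites")
        centre = float(v.mean())
        centres[name] = centre
        c = v - centre
        cols[name] = c
        ranges[name] = (float(c.min()), float(c.max()))
    for name in quadratic:
        cols[name + "2"] = cols[name] ** 2
    return PredictorSet(pd.DataFrame(cols, index=raw.index), centres, quadratic, ranges)
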