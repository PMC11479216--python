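"""Continuous input surfaces: IDW climate fields, terrain, distances.

* :func:`idw_interpolate` builds a temperature (or any station-value)
  surface by inverse-distance weighting; it is exact at station cells and
  its output never leaves the convex hull of the station values.
* :func:`slope_percent` / :func:`aspect_degrees` use Horn's 3x3 weighted
  finite differences on a square-grid DEM; borders are padded by odd
  reflection (linear extrapolation), so planes keep their gradient at the
  edges.  Aspect is the *downhill* bearing, degrees clockwise from north;
  flat cells are flagged -1.
* :func:`euclidean_distance` measures each cell centre's exact distance
  to the nearest vector feature (point-to-segment, no raster dilation);
  cells whose footprint intersects a feature are set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import correlate
from scipy.spatial.distance import cdist

from .grid import GridLayer

__all__ = [
    "StationRecord",
    "idw_interpolate",
    "mean_temperature",
    "slope_percent",
    "aspect_degrees",
    "euclidean_distance",
]


@dataclass(frozen=True)
class StationRecord:
    """One meteorological station with its annual mean temperatures."""

    name: str
    latitude: float
    longitude: float
    elevation: float
    annual_mean_min_temp: float
    annual_mean_max_temp: float

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"station {self.name}: latitude {self.latitude} out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"station {self.name}: longitude {self.longitude} out of range")


def idw_interpolate(
    stations,
    value_field: str,
    target_grid: GridLayer,
    *,
    power: float = 2.0,
    xy=None,
    eps: float = 1e-9,
) -> GridLayer:
    """Inverse-distance-weighted surface of a station attribute.

    ``stations`` is a sequence of :class:`StationRecord`; ``value_field``
    names the attribute to interpolate.  Station coordinates are taken
    from ``xy`` (sequence of planar (x, y) pairs in the grid's frame) if
    given, else from (longitude, latitude) directly — callers working on
    projected grids must pass projected ``xy``.

    A cell centre within ``eps`` of a station returns that station's
    value exactly.  All stations participate (no neighbourhood cutoff):
    with a handful of gauges truncation would gain nothing.
    """
    stations = list(stations)
    if not stations:
        raise ValueError("idw_interpolate needs at least one station")
    if power <= 0:
        raise ValueError("idw power must be positive")
    vals = np.array([float(getattr(s, value_field)) for s in stations])
    if xy is None:
        pts = np.array([[s.longitude, s.latitude] for s in stations], dtype=float)
    else:
        pts = np.asarray(xy, dtype=float)
    cx, cy = target_grid.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    d = cdist(centers, pts)
    at_station = d < eps
    with np.errstate(divide="ignore"):
        w = d**-power
    w[at_station] = np.inf
    # rows hitting a station: exact value; others: weighted mean
    out = np.empty(len(centers))
    hit = at_station.any(axis=1)
    out[hit] = vals[np.argmax(at_station[hit], axis=1)]
    ws = w[~hit]
    out[~hit] = (ws * vals).sum(axis=1) / ws.sum(axis=1)
    return target_grid.like(out.reshape(target_grid.shape), nodata=np.nan, units=value_field)


def mean_temperature(min_layer: GridLayer, max_layer: GridLayer) -> GridLayer:
    """Cellwise (min + max) / 2 with nodata propagation."""
    if not min_layer.same_grid(max_layer):
        raise ValueError("mean_temperature needs co-registered grids")
    valid = min_layer.valid_mask() & max_layer.valid_mask()
    out = np.where(
        valid,
        (np.asarray(min_layer.values, float) + np.asarray(max_layer.values, float)) / 2.0,
        np.nan,
    )
    return min_layer.like(out, nodata=np.nan, units="degC")


_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_HORN_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)  # +north


def _horn_gradient(dem: GridLayer) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(dem.values, dtype=float)
    px = dem.pixel_size
    # odd reflection extrapolates the border linearly, so affine surfaces
    # keep their exact gradient at the edges
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    gx = correlate(zp, _HORN_X, mode="nearest")[1:-1, 1:-1] / (8.0 * px)  # dz/dx, east +
    gy = correlate(zp, _HORN_Y, mode="nearest")[1:-1, 1:-1] / (8.0 * px)  # dz/dy, north +
    return gx, gy


def slope_percent(dem: GridLayer) -> GridLayer:
    """Slope as percent rise, 100 * |grad z|, Horn 3x3 stencil."""
    gx, gy = _horn_gradient(dem)
    slope = 100.0 * np.hypot(gx, gy)
    out = np.where(dem.valid_mask(), slope, np.nan)
    return dem.like(out, nodata=np.nan, units="percent")


def aspect_degrees(dem: GridLayer, *, flat_tol: float = 1e-12) -> GridLayer:
    """Downhill bearing in degrees clockwise from north; flat cells -1.

    A plane rising eastward drains west, so its aspect is 270.
    """
    gx, gy = _horn_gradient(dem)
    bearing = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    flat = np.hypot(gx, gy) < flat_tol
    out = np.where(flat, -1.0, bearing)
    out = np.where(dem.valid_mask(), out, np.nan)
    return dem.like(out, nodata=np.nan, units="degrees")


def euclidean_distance(target_grid: GridLayer, features) -> GridLayer:
    """Distance (m) from each cell centre to the nearest feature geometry.

    ``features`` is a sequence of shapely geometries (points/polylines) in
    the grid's planar frame.  Computed exactly per segment; cells whose
    square footprint intersects a feature are clamped to zero.
    """
    geoms = [g for g in features if g is not None and not g.is_empty]
    if not geoms:
        raise ValueError("euclidean_distance needs at least one non-empty feature")
    union = shapely.union_all(geoms)
    cx, cy = target_grid.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    d = shapely.distance(pts, union).reshape(target_grid.shape)

    # a feature can clip a cell corner while missing its centre
    px = target_grid.pixel_size
    near = (d > 0) & (d <= px * np.sqrt(2) / 2 + 1e-9)
    if near.any():
        rows, cols = np.nonzero(near)
        x0, y0 = target_grid.origin
        boxes = shapely.box(
            x0 + cols * px, y0 - (rows + 1) * px, x0 + (cols + 1) * px, y0 - rows * px
        )
        hit = shapely.intersects(boxes, union)
        d[rows[hit], cols[hit]] = 0.0
    out = np.where(target_grid.valid_mask(), d, np.nan)
    return target_grid.like(out, nodata=np.nan, units="m")
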