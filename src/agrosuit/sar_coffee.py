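"""Coffee mapping from calibrated SAR backscatter (dB).

Shaded coffee confuses optical classifiers, but its canopy structure
gives it a characteristic C-band backscatter level.  The procedure:
sample the dB scene at ground-truth coffee locations, take the sampled
value range (optionally trimmed) as a closed threshold interval, and
flag every scene cell inside it as coffee.  Works on any single
preprocessed dB band regardless of date or polarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridLayer

__all__ = [
    "ThresholdInterval",
    "extract_values_at_points",
    "derive_threshold",
    "threshold_mask",
    "jaccard",
]

MASK_NODATA = 255


@dataclass(frozen=True)
class ThresholdInterval:
    low_db: float
    high_db: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.low_db <= self.high_db:
            raise ValueError(f"empty interval [{self.low_db}, {self.high_db}]")
        if self.n_points < 1:
            raise ValueError("an interval needs at least one supporting point")


def extract_values_at_points(layer: GridLayer, points):
    """Sample the cell value under each (x, y) point, no interpolation.

    Returns ``(samples, nodata_points)``: samples is a list of
    ``((x, y), value)`` for points on valid cells, nodata_points the
    points that fell on nodata cells (excluded from threshold
    derivation).  A point outside the raster extent raises.
    """
    outside = [p for p in points if not layer.contains(p[0], p[1])]
    if outside:
        raise ValueError(f"points outside raster extent {layer.bounds}: {outside}")
    valid = layer.valid_mask()
    samples, on_nodata = [], []
    for p in points:
        x, y = float(p[0]), float(p[1])
        r, c = layer.point_to_rowcol(x, y)
        if valid[r, c]:
            samples.append(((x, y), float(layer.values[r, c])))
        else:
            on_nodata.append((x, y))
    return samples, on_nodata


def derive_threshold(values, trim_fraction: float = 0.0) -> ThresholdInterval:
    """Threshold interval from sampled dB values.

    With ``trim_fraction`` 0 (default) this is the exact sampled
    min/max; otherwise the symmetric quantiles, guarding against
    outlying ground-truth samples.
    """
    v = np.asarray([x for x in np.atleast_1d(np.asarray(values, dtype=float)) if np.isfinite(x)])
    if v.size == 0:
        raise ValueError("derive_threshold needs at least one finite value")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if trim_fraction == 0:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo = float(np.quantile(v, trim_fraction))
        hi = float(np.quantile(v, 1.0 - trim_fraction))
    return ThresholdInterval(low_db=lo, high_db=hi, n_points=int(v.size))


def threshold_mask(layer: GridLayer, interval: ThresholdInterval) -> tuple[GridLayer, float]:
    """Binary coffee mask (closed interval) and its area in km^2."""
    v = np.asarray(layer.values, dtype=float)
    valid = layer.valid_mask()
    inside = valid & (v >= interval.low_db) & (v <= interval.high_db)
    mask = np.where(valid, inside.astype(np.uint8), MASK_NODATA).astype(np.uint8)
    area_km2 = float(inside.sum()) * layer.pixel_size**2 / 1e6
    return layer.like(mask, nodata=MASK_NODATA, units="mask"), area_km2


def jaccard(mask_a: GridLayer | np.ndarray, mask_b: GridLayer | np.ndarray) -> float:
    """Intersection-over-union of two binary masks (nodata excluded)."""

    def _bool(m):
        if isinstance(m, GridLayer):
            return (np.asarray(m.values) == 1) & m.valid_mask()
        return np.asarray(m).astype(bool)

    a, b = _bool(mask_a), _bool(mask_b)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)
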