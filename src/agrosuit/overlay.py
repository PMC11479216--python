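"""Weighted overlay of score layers into the suitability surface.

The suitability score at each pixel is the weighted linear combination
``PACP = sum_i w_i x_i`` over the 14 criterion score layers ``x_i``
(values 1/2/3) with AHP weights ``w_i`` summing to 1, so valid PACP
cells lie in [1, 3].  The continuous surface is then cut into
unsuitable / sub-suitable / suitable classes at configurable breaks
(default: equal-width thirds of [1, 3]) and class areas are tabulated.
Accuracy helpers (confusion matrix, overall accuracy, Cohen's kappa)
support validation against reference data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import SCORE_NODATA
from .grid import GridLayer, require_same_grid

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_BREAKS",
    "SuitabilityResult",
    "ConfusionMatrix",
    "weighted_overlay",
    "classify_suitability",
    "tabulate_areas",
    "accuracy_metrics",
    "validate_points",
]

CLASS_NAMES = {1: "Unsuitable", 2: "Sub-suitable", 3: "Suitable"}
DEFAULT_BREAKS = (5.0 / 3.0, 7.0 / 3.0)


@dataclass
class SuitabilityResult:
    pacp: GridLayer
    classes: GridLayer
    area_table: pd.DataFrame
    breaks: tuple[float, float] = DEFAULT_BREAKS


@dataclass(frozen=True)
class ConfusionMatrix:
    """Reference (rows) x predicted (columns) count table."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.labels)
        if c.shape != (n, n):
            raise ValueError("confusion matrix must be square over the labels")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def weighted_overlay(score_layers: dict[str, GridLayer], weights: dict[str, float]) -> GridLayer:
    """PACP surface: per-cell dot product of scores and weights.

    All layers must share one grid and the weight keys must match the
    layer names exactly; weights must sum to 1 within 1e-6.  Any nodata
    input voids the cell (strict propagation — a silently dropped
    criterion would under-weight the score).
    """
    if set(score_layers) != set(weights):
        raise ValueError(
            f"weight keys do not match layer names: only-layers "
            f"{sorted(set(score_layers) - set(weights))}, only-weights "
            f"{sorted(set(weights) - set(score_layers))}"
        )
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {wsum!r}, expected 1 within 1e-6")
    require_same_grid(score_layers)
    names = sorted(score_layers)
    ref = score_layers[names[0]]
    valid = np.all([score_layers[n].valid_mask() for n in names], axis=0)
    # accumulate in sorted-name order: bit-reproducible and identical to a
    # per-cell loop over the same ordering
    pacp = np.zeros(ref.shape, dtype=float)
    for n in names:
        pacp += weights[n] * np.asarray(score_layers[n].values, dtype=float)
    out = np.where(valid, pacp, np.nan)
    return ref.like(out, nodata=np.nan, units="PACP")


def classify_suitability(pacp: GridLayer, breaks: tuple[float, float] = DEFAULT_BREAKS) -> GridLayer:
    """Cut PACP into classes 1/2/3 at (b1, b2): 1 below b1, 3 at/above b2."""
    b1, b2 = breaks
    if not 1.0 < b1 < b2 < 3.0:
        raise ValueError(f"breaks must satisfy 1 < b1 < b2 < 3, got {breaks}")
    v = np.asarray(pacp.values, dtype=float)
    valid = pacp.valid_mask()
    cls = np.full(v.shape, 1, dtype=np.int16)
    cls[v >= b1] = 2
    cls[v >= b2] = 3
    out = np.where(valid, cls, SCORE_NODATA).astype(np.uint8)
    return pacp.like(out, nodata=SCORE_NODATA, units="class")


def tabulate_areas(classes: GridLayer, pixel_size: float | None = None) -> pd.DataFrame:
    """Per-class area (km^2, %) plus a total row over valid cells."""
    px = classes.pixel_size if pixel_size is None else pixel_size
    v = np.asarray(classes.values)
    valid = classes.valid_mask()
    total_cells = int(valid.sum())
    rows = []
    for code, name in CLASS_NAMES.items():
        n = int((valid & (v == code)).sum())
        area = n * px**2 / 1e6
        pct = 100.0 * n / total_cells if total_cells else 0.0
        rows.append({"class": name, "code": code, "area_km2": area, "percent": pct})
    if total_cells == 0:
        return pd.DataFrame(
            [{"class": "Total", "code": 0, "area_km2": 0.0, "percent": 0.0}]
        )
    rows.append(
        {
            "class": "Total",
            "code": 0,
            "area_km2": total_cells * px**2 / 1e6,
            "percent": 100.0,
        }
    )
    return pd.DataFrame(rows)


def accuracy_metrics(confusion: ConfusionMatrix) -> tuple[float, float | None]:
    """Overall accuracy (trace/total) and Cohen's kappa.

    Kappa is ``(po - pe) / (1 - pe)`` with the chance agreement ``pe``
    from the row/column marginals; when pe = 1 (all mass in one marginal
    cell) kappa is undefined and reported as None.
    """
    c = np.asarray(confusion.counts, dtype=float)
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if abs(1.0 - pe) < 1e-12:
        return float(po), None
    return float(po), float((po - pe) / (1.0 - pe))


def validate_points(classes: GridLayer, labelled_points) -> pd.DataFrame:
    """Overlay labelled field points on the class raster.

    ``labelled_points`` is a sequence of (x, y) or (x, y, label).
    Returns one row per point with the predicted class name (or
    'unscored' on nodata).
    """
    rows = []
    valid = classes.valid_mask()
    for p in labelled_points:
        x, y = float(p[0]), float(p[1])
        label = p[2] if len(p) > 2 else None
        if not classes.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        r, c = classes.point_to_rowcol(x, y)
        if valid[r, c]:
            code = int(classes.values[r, c])
            rows.append({"x": x, "y": y, "label": label, "predicted_code": code,
                         "predicted": CLASS_NAMES.get(code, str(code))})
        else:
            rows.append({"x": x, "y": y, "label": label, "predicted_code": None,
                         "predicted": "unscored"})
    return pd.DataFrame(rows)
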