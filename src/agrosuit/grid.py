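"""Single-band raster container used throughout the pipeline.

Conventions (asserted in the I/O round-trip tests):

* arrays are row-major with 0-based indices, row 0 at the *top* of the map;
* ``origin`` is the (x, y) map coordinate of the top-left corner of the
  top-left cell, so cell (r, c) spans
  ``[x0 + c*px, x0 + (c+1)*px) x (y0 - (r+1)*px, y0 - r*px]``;
* point sampling refers to these half-open footprints: a point on a shared
  vertical edge belongs to the cell on the right, a point on a shared
  horizontal edge to the cell below (top edge inclusive);
* cell *centres* are used wherever a cell is treated as a point (IDW,
  distance rasters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridLayer", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


@dataclass
class GridLayer:
    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    units: str = ""
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nr * self.pixel_size, x0 + nc * self.pixel_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every cell centre as 2-D (x, y) arrays."""
        nr, nc = self.shape
        x0, y0 = self.origin
        px = self.pixel_size
        xs = x0 + (np.arange(nc) + 0.5) * px
        ys = y0 - (np.arange(nr) + 0.5) * px
        return np.meshgrid(xs, ys)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin < y <= ymax

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Cell holding a point under the half-open footprint convention."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.bounds}")
        x0, y0 = self.origin
        px = self.pixel_size
        col = int(np.floor((x - x0) / px))
        row = int(np.floor((y0 - y) / px))
        nr, nc = self.shape
        # top edge of row 0 is inclusive
        if row == nr:
            row -= 1
        return min(row, nr - 1), min(col, nc - 1)

    # -- masks and derivation -------------------------------------------
    def valid_mask(self) -> np.ndarray:
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            mask = np.isfinite(v)
            if self.nodata is not None and np.isfinite(self.nodata):
                mask &= v != self.nodata
            return mask
        if self.nodata is None:
            return np.ones(v.shape, dtype=bool)
        return v != self.nodata

    def like(self, values: np.ndarray, *, nodata=None, units: str = "") -> "GridLayer":
        """New layer on this layer's grid with different values."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("derived values must match the grid shape")
        return GridLayer(
            values=np.asarray(values),
            pixel_size=self.pixel_size,
            origin=self.origin,
            nodata=nodata,
            units=units,
            crs_tag=self.crs_tag,
        )

    def same_grid(self, other: "GridLayer", *, rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-6)
        )


def require_same_grid(layers: dict[str, GridLayer]) -> None:
    """Raise GridMismatchError naming the first layer off the common grid."""
    items = list(layers.items())
    ref_name, ref = items[0]
    for name, layer in items[1:]:
        if not ref.same_grid(layer):
            raise GridMismatchError(
                f"layer {name!r} is not co-registered with {ref_name!r} "
                f"(shape {layer.shape} px {layer.pixel_size} origin {layer.origin} "
                f"vs {ref.shape} px {ref.pixel_size} origin {ref.origin})"
            )
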