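"""Readers/writers: ASCII-grid rasters, CSV tables, GeoJSON features.

Rasters use the ESRI ASCII grid format (plain text: ncols/nrows,
lower-left corner, cellsize, nodata, then rows top to bottom), which
round-trips the GridLayer georeferencing exactly.  Vector features use
GeoJSON through shapely; tables use CSV through pandas.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import shapely

from .ahp import HierarchyModel, parse_judgment, validate_reciprocal
from .grid import GridLayer
from .surfaces import StationRecord

__all__ = [
    "read_grid", "write_grid",
    "read_stations_csv", "default_stations",
    "read_points_csv", "write_points_csv",
    "read_features_geojson", "write_features_geojson",
    "read_matrix_csv", "read_hierarchy_yaml",
]


def _mkparent(path) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)


def write_grid(layer: GridLayer, path, *, fmt: str = "%.10g") -> None:
    """Write a GridLayer as an ESRI ASCII grid (text)."""
    _mkparent(path)
    nr, nc = layer.shape
    x0, y0 = layer.origin
    nodata = layer.nodata
    vals = np.asarray(layer.values, dtype=float)
    if nodata is None or (isinstance(nodata, float) and np.isnan(nodata)):
        nodata_out = -9999.0
        vals = np.where(np.isfinite(vals), vals, nodata_out)
    else:
        nodata_out = float(nodata)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {x0!r}\nyllcorner {y0 - nr * layer.pixel_size!r}\n"
        f"cellsize {layer.pixel_size!r}\nNODATA_value {nodata_out!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_grid(path, *, units: str = "", crs_tag: str = "local") -> GridLayer:
    """Read an ESRI ASCII grid; nodata cells become NaN (float data)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in meta:
            raise ValueError(f"{path}: missing georeferencing field {key!r}")
    nr, nc = int(meta["nrows"]), int(meta["ncols"])
    if vals.shape != (nr, nc):
        raise ValueError(f"{path}: data shape {vals.shape} does not match header ({nr}, {nc})")
    nodata = meta.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    px = meta["cellsize"]
    origin = (meta["xllcorner"], meta["yllcorner"] + nr * px)
    return GridLayer(values=vals, pixel_size=px, origin=origin, nodata=np.nan,
                     units=units, crs_tag=crs_tag)


def read_stations_csv(path) -> list[StationRecord]:
    df = pd.read_csv(path)
    return [
        StationRecord(
            name=str(r["name"]),
            latitude=float(r["latitude"]),
            longitude=float(r["longitude"]),
            elevation=float(r["elevation"]),
            annual_mean_min_temp=float(r["annual_mean_min_temp"]),
            annual_mean_max_temp=float(r["annual_mean_max_temp"]),
        )
        for _, r in df.iterrows()
    ]


def default_stations() -> list[StationRecord]:
    """The packaged Gedeo gauge-station table."""
    from importlib import resources

    with resources.as_file(resources.files("agrosuit.data") / "stations_gedeo.csv") as p:
        return read_stations_csv(p)


def read_points_csv(path) -> list[tuple]:
    df = pd.read_csv(path)
    if "label" in df.columns:
        return [(float(r["x"]), float(r["y"]), r["label"]) for _, r in df.iterrows()]
    return [(float(r["x"]), float(r["y"])) for _, r in df.iterrows()]


def write_points_csv(points, path) -> None:
    _mkparent(path)
    rows = [
        {"x": p[0], "y": p[1], **({"label": p[2]} if len(p) > 2 else {})} for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_features_geojson(geoms, path, *, kind: str = "") -> None:
    _mkparent(path)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(g)),
                "properties": {"kind": kind} if kind else {},
            }
            for g in geoms
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_features_geojson(path) -> list:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        return [shapely.geometry.shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [shapely.geometry.shape(doc["geometry"])]
    return [shapely.geometry.shape(doc)]


def read_matrix_csv(path):
    """Pairwise matrix CSV: header row/column of labels, 'p/q' cells allowed."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c).strip() for c in df.columns]
    row_labels = [str(i).strip() for i in df.index]
    if labels != row_labels:
        raise ValueError(f"{path}: row labels {row_labels} != column labels {labels}")
    entries = [[parse_judgment(v) if not pd.isna(v) else None for v in row]
               for row in df.values]
    return validate_reciprocal(entries, labels)


def read_hierarchy_yaml(path) -> HierarchyModel:
    """Hierarchy config: inline main matrix plus one sub-matrix per main
    criterion (labels + rows, 'p/q' strings allowed)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def build(node):
        return validate_reciprocal(
            node["rows"], node["labels"], strict=node.get("strict", True)
        )

    main = build(doc["main"])
    subs = {name: build(node) for name, node in doc.get("subs", {}).items()}
    return HierarchyModel(main=main, subs=subs)
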