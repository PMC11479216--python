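"""Seeded synthetic landscape with the structure the analysis assumes.

Generates the full 14-layer thematic stack for a Gedeo-like highland
landscape — elevation 1329-3088 m, rainfall 1093.02-1667 mm, SOM 0-6 %,
CEC 0-43 cmol+/kg, acidic soils, six land-cover classes dominated by
agroforestry and farmland — together with meteorological stations,
road/river polylines, a SAR backscatter scene whose coffee patches sit
in the field-observed dB interval [-19.034781, -10.773612], and
ground-truth coffee points.  Every stage of the suitability pipeline is
therefore testable offline with known ground truth.

Construction choices:

* continuous fields are Gaussian-filtered white noise affinely rescaled
  to the configured range — simple, seedable, spatially smooth;
* min/max temperature are affine in elevation (configurable lapse rates
  anchored at a reference elevation) plus small noise, reproducing the
  strong negative elevation-temperature coupling of highland climate;
* land cover is carved from a smooth field by quantile thresholding, so
  class proportions hit their targets to within ties and classes form
  contiguous patches;
* coffee patches are placed inside agroforestry cells; the ground-truth
  sample always includes the cells holding the scene's lowest and
  highest coffee dB, mirroring field campaigns that bracket the
  backscatter range, so the derived min/max threshold spans every patch
  cell.

Also provides the worked pairwise-judgment matrices of the coffee
suitability hierarchy as fixtures (:func:`generate_worked_matrices`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter

from .ahp import HierarchyModel, validate_reciprocal
from .grid import GridLayer
from .surfaces import StationRecord, aspect_degrees, euclidean_distance, slope_percent

__all__ = ["LandscapeConfig", "Landscape", "generate_landscape", "generate_worked_matrices",
           "LULC_LEGEND", "TEXTURE_LEGEND"]

#: integer code -> class name for the generated categorical layers
LULC_LEGEND = {1: "farmland", 2: "agroforestry", 3: "forest",
               4: "grassland", 5: "settlement", 6: "wetland"}
TEXTURE_LEGEND = {1: "C", 2: "L", 3: "SL"}

#: land-cover proportions of the reference-year map (fractions of area)
DEFAULT_LULC_PROPORTIONS = {
    "farmland": 0.4134,
    "agroforestry": 0.4454,
    "forest": 0.0733,
    "grassland": 0.0072,
    "settlement": 0.0485,
    "wetland": 0.0122,
}

#: clay / loam / sandy-loam split of the mapped soil textures
DEFAULT_TEXTURE_PROPORTIONS = {"C": 0.053, "L": 0.282, "SL": 0.665}


@dataclass
class LandscapeConfig:
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 10.0
    seed: int = 0
    elevation_range: tuple[float, float] = (1329.0, 3088.0)
    rainfall_range: tuple[float, float] = (1093.02, 1667.0)
    som_range: tuple[float, float] = (0.0, 6.0)
    cec_range: tuple[float, float] = (0.0, 43.0)
    ph_range: tuple[float, float] = (4.0, 7.5)
    lulc_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LULC_PROPORTIONS)
    )
    texture_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_PROPORTIONS)
    )
    coffee_db_interval: tuple[float, float] = (-19.034781, -10.773612)
    background_db_interval: tuple[float, float] = (-9.5, -4.0)
    n_stations: int = 6
    n_ground_truth: int = 50
    #: degC lost per metre climbed; min-temp lapse from the station table,
    #: max-temp lapse slightly steeper as observed between valley and ridge
    lapse_rate_min: float = 0.0044
    lapse_rate_max: float = 0.0068
    temp_anchor: tuple[float, float, float] = (1515.0, 12.7, 28.0)  # (elev, minT, maxT)
    temp_noise_sd: float = 0.1
    db_noise_sd: float = 0.0
    smooth_sigma: float = 8.0
    coffee_patch_fraction: float = 0.45  # of agroforestry cells
    n_roads: int = 2
    n_rivers: int = 2

    def __post_init__(self) -> None:
        psum = sum(self.lulc_proportions.values())
        if abs(psum - 1.0) > 1e-6:
            raise ValueError(f"LULC proportions sum to {psum}, expected 1")
        lo, hi = self.coffee_db_interval
        blo, bhi = self.background_db_interval
        if not (bhi < lo or blo > hi):
            raise ValueError("coffee and background dB intervals must be disjoint")
        n_cells = self.shape[0] * self.shape[1]
        if min(self.lulc_proportions.values()) * n_cells < 1:
            raise ValueError("grid too small for the smallest LULC class")


@dataclass
class Landscape:
    """Everything the pipeline consumes, plus generator ground truth."""

    config: LandscapeConfig
    layers: dict[str, GridLayer]            # the 14 criterion input layers
    legends: dict[str, dict[int, str]]      # for categorical layers
    stations: list[StationRecord]
    station_xy: list[tuple[float, float]]   # planar coords on the grid
    roads: list
    rivers: list
    sar_db: GridLayer
    coffee_truth: np.ndarray                # boolean patch stencil
    ground_truth_points: list[tuple[float, float]]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.layers):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.layers[name].values).tobytes())
        h.update(np.ascontiguousarray(self.sar_db.values).tobytes())
        h.update(np.ascontiguousarray(self.coffee_truth).tobytes())
        for x, y in self.ground_truth_points:
            h.update(np.float64(x).tobytes())
            h.update(np.float64(y).tobytes())
        for s in self.stations:
            h.update(repr(s).encode())
        for g in [*self.roads, *self.rivers]:
            h.update(shapely.to_wkb(g))
        return h.hexdigest()


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return f


def _rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full_like(f, (lo + hi) / 2.0)
    return lo + (f - fmin) * (hi - lo) / (fmax - fmin)


def _categorical_from_field(f: np.ndarray, proportions: dict[str, float],
                            legend: dict[int, str]) -> np.ndarray:
    """Quantile-threshold a smooth field into classes at target proportions."""
    name_to_code = {v: k for k, v in legend.items()}
    order = sorted(proportions, key=proportions.get, reverse=True)
    cum, edges = 0.0, []
    for name in order[:-1]:
        cum += proportions[name]
        edges.append(np.quantile(f, cum))
    codes = np.empty(f.shape, dtype=np.int16)
    prev = -np.inf
    for name, edge in zip(order, edges + [np.inf]):
        codes[(f > prev) & (f <= edge)] = name_to_code[name]
        prev = edge
    return codes


def _random_polyline(rng: np.random.Generator, bounds, n_vertices: int = 8):
    xmin, ymin, xmax, ymax = bounds
    # a wandering line spanning the extent horizontally or vertically
    if rng.random() < 0.5:
        xs = np.linspace(xmin, xmax, n_vertices)
        ys = rng.uniform(ymin, ymax, n_vertices)
    else:
        ys = np.linspace(ymin, ymax, n_vertices)
        xs = rng.uniform(xmin, xmax, n_vertices)
    return shapely.LineString(np.column_stack([xs, ys]))


def generate_landscape(config: LandscapeConfig | None = None) -> Landscape:
    """Build the full synthetic layer stack; byte-identical per seed."""
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.shape
    px = cfg.pixel_size
    origin = (0.0, nr * px)

    def layer(vals, units=""):
        return GridLayer(values=vals, pixel_size=px, origin=origin, nodata=np.nan, units=units)

    # terrain
    dem_vals = _rescale(_smooth_field(rng, cfg.shape, cfg.smooth_sigma), *cfg.elevation_range)
    dem = layer(dem_vals, "m")
    slope = slope_percent(dem)
    aspect = aspect_degrees(dem)

    # climate: temperature affine in elevation + noise, rainfall independent
    e0, t_min0, t_max0 = cfg.temp_anchor
    min_t = t_min0 - cfg.lapse_rate_min * (dem_vals - e0) + cfg.temp_noise_sd * rng.standard_normal(cfg.shape)
    max_t = t_max0 - cfg.lapse_rate_max * (dem_vals - e0) + cfg.temp_noise_sd * rng.standard_normal(cfg.shape)
    avg_t = (min_t + max_t) / 2.0
    rain = _rescale(_smooth_field(rng, cfg.shape, cfg.smooth_sigma), *cfg.rainfall_range)

    # soils
    som = _rescale(_smooth_field(rng, cfg.shape, cfg.smooth_sigma), *cfg.som_range)
    cec = _rescale(_smooth_field(rng, cfg.shape, cfg.smooth_sigma), *cfg.cec_range)
    ph = _rescale(_smooth_field(rng, cfg.shape, cfg.smooth_sigma), *cfg.ph_range)
    texture = _categorical_from_field(
        _smooth_field(rng, cfg.shape, cfg.smooth_sigma), cfg.texture_proportions, TEXTURE_LEGEND
    )

    # land cover
    lulc = _categorical_from_field(
        _smooth_field(rng, cfg.shape, cfg.smooth_sigma), cfg.lulc_proportions, LULC_LEGEND
    )

    # access features and distance layers
    xmin, ymin, xmax, ymax = (0.0, 0.0, nc * px, nr * px)
    roads = [_random_polyline(rng, (xmin, ymin, xmax, ymax)) for _ in range(cfg.n_roads)]
    rivers = [_random_polyline(rng, (xmin, ymin, xmax, ymax)) for _ in range(cfg.n_rivers)]
    dist_road = euclidean_distance(dem, roads)
    dist_river = euclidean_distance(dem, rivers)

    # stations at random cells, reading the generated temperature fields
    # there, so interpolation tests have exact ground truth
    stations, station_xy = [], []
    cells = rng.choice(nr * nc, size=cfg.n_stations, replace=False)
    for k, cell in enumerate(cells):
        r, c = divmod(int(cell), nc)
        x = origin[0] + (c + 0.5) * px
        y = origin[1] - (r + 0.5) * px
        station_xy.append((x, y))
        stations.append(
            StationRecord(
                name=f"station_{k}",
                latitude=float(np.clip(y / 111_000.0, -90, 90)),
                longitude=float(np.clip(x / 111_000.0, -180, 180)),
                elevation=float(dem_vals[r, c]),
                annual_mean_min_temp=float(min_t[r, c]),
                annual_mean_max_temp=float(max_t[r, c]),
            )
        )

    # SAR scene: coffee patches carved from agroforestry cells
    agro = lulc == 2
    patch_field = _smooth_field(rng, cfg.shape, cfg.smooth_sigma / 2)
    if agro.any():
        cut = np.quantile(patch_field[agro], 1.0 - cfg.coffee_patch_fraction)
        coffee = agro & (patch_field > cut)
        if not coffee.any():  # degenerate quantile tie
            coffee = agro.copy()
    else:
        coffee = np.zeros(cfg.shape, dtype=bool)
    lo, hi = cfg.coffee_db_interval
    margin = 0.05 * (hi - lo)
    db = rng.uniform(*cfg.background_db_interval, size=cfg.shape)
    db[coffee] = rng.uniform(lo + margin, hi - margin, size=int(coffee.sum()))
    if cfg.db_noise_sd > 0:
        db = db + rng.normal(0.0, cfg.db_noise_sd, size=cfg.shape)
        # keep the scene separable: patches stay inside the interval,
        # background stays outside it
        db[coffee] = np.clip(db[coffee], lo, hi)
        bg = ~coffee
        blo, bhi = cfg.background_db_interval
        if bhi < lo:
            db[bg] = np.clip(db[bg], -np.inf, min(bhi, lo - 1e-6))
        else:
            db[bg] = np.clip(db[bg], max(blo, hi + 1e-6), np.inf)
    sar = layer(db, "dB")

    # ground-truth points inside patches, always covering the dB extremes
    points: list[tuple[float, float]] = []
    if coffee.any():
        idx = np.flatnonzero(coffee)
        flat_db = db.ravel()
        extremes = [idx[np.argmin(flat_db[idx])], idx[np.argmax(flat_db[idx])]]
        n_rand = max(cfg.n_ground_truth - len(extremes), 0)
        chosen = list(rng.choice(idx, size=min(n_rand, idx.size), replace=False)) + extremes
        for cell in chosen:
            r, c = divmod(int(cell), nc)
            points.append((origin[0] + (c + 0.5) * px, origin[1] - (r + 0.5) * px))

    layers = {
        "elevation": dem,
        "slope": slope,
        "aspect": aspect,
        "rainfall": layer(rain, "mm"),
        "avg_temp": layer(avg_t, "degC"),
        "min_temp": layer(min_t, "degC"),
        "max_temp": layer(max_t, "degC"),
        "som": layer(som, "percent"),
        "cec": layer(cec, "cmol+/kg"),
        "ph": layer(ph, "pH"),
        "texture": GridLayer(values=texture, pixel_size=px, origin=origin, nodata=-1,
                             units="texture class"),
        "lulc": GridLayer(values=lulc, pixel_size=px, origin=origin, nodata=-1,
                          units="LULC class"),
        "dist_road": dist_road,
        "dist_river": dist_river,
    }
    return Landscape(
        config=cfg,
        layers=layers,
        legends={"lulc": dict(LULC_LEGEND), "texture": dict(TEXTURE_LEGEND)},
        stations=stations,
        station_xy=station_xy,
        roads=roads,
        rivers=rivers,
        sar_db=sar,
        coffee_truth=coffee,
        ground_truth_points=points,
    )


# -- worked judgment matrices ------------------------------------------

def generate_worked_matrices() -> HierarchyModel:
    """The coffee-suitability judgment hierarchy: one 4x4 main matrix and
    four sub-matrices over the 14 thematic criteria, exactly as elicited
    from the expert comparisons."""
    main = validate_reciprocal(
        [
            [1, 5, 4, 5],
            ["1/5", 1, "3/2", "3/2"],
            ["1/4", "2/3", 1, 2],
            ["1/5", "2/3", "1/2", 1],
        ],
        ["climatology", "edaphic", "physiographic", "socioeconomic"],
    )
    # the elicited table records avg_temp-vs-max_temp asymmetrically
    # (2 one way, 2/3 the other); the published priorities derive from
    # it verbatim, so it is validated in non-strict mode
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        climato = validate_reciprocal(
            [
                [1, "2/3", 2, "3/2"],
                ["3/2", 1, 3, 2],
                ["1/2", "1/3", 1, "2/3"],
                ["2/3", "2/3", "3/2", 1],
            ],
            ["rainfall", "avg_temp", "min_temp", "max_temp"],
            strict=False,
        )
    edaphic = validate_reciprocal(
        [
            [1, "3/2", 2, 2],
            ["2/3", 1, "3/2", 2],
            ["1/2", "2/3", 1, "3/2"],
            ["1/2", "1/2", "2/3", 1],
        ],
        ["ph", "texture", "cec", "som"],
    )
    physio = validate_reciprocal(
        [
            [1, 3, 5],
            ["1/3", 1, "3/2"],
            ["1/5", "2/3", 1],
        ],
        ["elevation", "slope", "aspect"],
    )
    socio = validate_reciprocal(
        [
            [1, 3, 3],
            ["1/3", 1, "3/2"],
            ["1/3", "2/3", 1],
        ],
        ["lulc", "dist_road", "dist_river"],
    )
    return HierarchyModel(
        main=main,
        subs={
            "climatology": climato,
            "edaphic": edaphic,
            "physiographic": physio,
            "socioeconomic": socio,
        },
    )
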