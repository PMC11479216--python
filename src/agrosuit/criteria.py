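"""Reclassify thematic layers into 1/2/3 suitability scores.

Each criterion carries an ordered rule list mapping value intervals
(continuous layers) or category sets (categorical layers) to a score:
3 = suitable, 2 = sub-suitable, 1 = unsuitable.  The default coffee rule
set shipped in ``data/criteria_coffee.yaml`` encodes published crop
requirements for Coffea arabica (rainfall, temperatures, soil chemistry
and texture, terrain, land cover, access distances).

Interval bounds carry explicit closure flags.  The shipped rules close
each shared boundary on the side of the *better* class, so e.g. 1600 mm
rainfall and a pH of exactly 7.5 both take the higher of the two adjacent
scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .grid import GridLayer

__all__ = [
    "ContinuousRule",
    "CategoryRule",
    "CriterionSpec",
    "ReclassifyError",
    "load_criteria",
    "reclassify_continuous",
    "reclassify_categorical",
    "reclassify",
    "classify_agroecology",
    "aspect_to_score",
    "AGRO_ZONES",
    "SCORE_NODATA",
]

SCORE_NODATA = 255  # uint8 sentinel for score rasters

VALID_SCORES = (1, 2, 3)


class ReclassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ContinuousRule:
    score: int
    lo: float = -math.inf
    hi: float = math.inf
    closed_lo: bool = True
    closed_hi: bool = False

    def mask(self, v: np.ndarray) -> np.ndarray:
        m_lo = v >= self.lo if self.closed_lo else v > self.lo
        m_hi = v <= self.hi if self.closed_hi else v < self.hi
        return m_lo & m_hi


@dataclass(frozen=True)
class CategoryRule:
    score: int
    categories: frozenset[str]


@dataclass
class CriterionSpec:
    name: str
    kind: str  # "continuous" | "categorical" | "aspect"
    rules: list = field(default_factory=list)
    default_score: int | None = None
    weight: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        for r in self.rules:
            if r.score not in VALID_SCORES:
                raise ReclassifyError(f"{self.name}: rule score {r.score} not in {VALID_SCORES}")
        if self.default_score is not None and self.default_score not in VALID_SCORES:
            raise ReclassifyError(f"{self.name}: default score {self.default_score} invalid")


def _rules_from_yaml(name: str, kind: str, raw_rules: list[dict]) -> list:
    rules = []
    for r in raw_rules:
        if kind == "continuous":
            rules.append(
                ContinuousRule(
                    score=int(r["score"]),
                    lo=float(r.get("min", -math.inf)),
                    hi=float(r.get("max", math.inf)),
                    closed_lo=bool(r.get("closed_min", True)),
                    closed_hi=bool(r.get("closed_max", False)),
                )
            )
        elif kind == "categorical":
            rules.append(CategoryRule(score=int(r["score"]), categories=frozenset(r["categories"])))
        else:
            raise ReclassifyError(f"{name}: unknown rule kind {kind!r}")
    return rules


def load_criteria(path=None) -> dict[str, CriterionSpec]:
    """Load a criterion rule file; defaults to the shipped coffee rules."""
    if path is None:
        text = resources.files("agrosuit.data").joinpath("criteria_coffee.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    specs: dict[str, CriterionSpec] = {}
    for name, entry in doc["criteria"].items():
        kind = entry["kind"]
        rules = [] if kind == "aspect" else _rules_from_yaml(name, kind, entry.get("rules", []))
        specs[name] = CriterionSpec(
            name=name,
            kind=kind,
            rules=rules,
            default_score=entry.get("default_score"),
            units=entry.get("units", ""),
        )
    return specs


def _score_output(layer: GridLayer, scores: np.ndarray, valid: np.ndarray) -> GridLayer:
    out = np.where(valid, scores, SCORE_NODATA).astype(np.uint8)
    return layer.like(out, nodata=SCORE_NODATA, units="score")


def reclassify_continuous(layer: GridLayer, spec: CriterionSpec) -> GridLayer:
    """Map a continuous layer to scores via the spec's interval rules."""
    if spec.kind != "continuous":
        raise ReclassifyError(f"{spec.name}: reclassify_continuous needs a continuous spec")
    v = np.asarray(layer.values, dtype=float)
    valid = layer.valid_mask()
    scores = np.zeros(v.shape, dtype=np.int16)
    unassigned = valid.copy()
    for rule in spec.rules:
        hit = unassigned & rule.mask(v)
        scores[hit] = rule.score
        unassigned &= ~hit
    if unassigned.any():
        if spec.default_score is None:
            bad = float(v[unassigned][0])
            raise ReclassifyError(f"{spec.name}: value {bad} matches no rule and no default score is set")
        scores[unassigned] = spec.default_score
    return _score_output(layer, scores, valid)


def reclassify_categorical(layer: GridLayer, spec: CriterionSpec, legend: dict[int, str]) -> GridLayer:
    """Map an integer-coded categorical layer to scores via its legend."""
    if spec.kind != "categorical":
        raise ReclassifyError(f"{spec.name}: reclassify_categorical needs a categorical spec")
    v = np.asarray(layer.values)
    valid = layer.valid_mask()
    cat_score: dict[str, int] = {}
    for rule in spec.rules:
        for c in rule.categories:
            cat_score[c] = rule.score
    scores = np.zeros(v.shape, dtype=np.int16)
    unassigned = valid.copy()
    for code in np.unique(v[valid]):
        cells = valid & (v == code)
        name = legend.get(int(code))
        if name is None or name not in cat_score:
            if spec.default_score is None:
                label = name if name is not None else f"code {int(code)}"
                raise ReclassifyError(f"{spec.name}: unknown category {label!r} and no default score is set")
            scores[cells] = spec.default_score
        else:
            scores[cells] = cat_score[name]
        unassigned &= ~cells
    return _score_output(layer, scores, valid)


# -- terrain aspect ----------------------------------------------------

#: 45-degree compass sectors centred on the eight bearings.
_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
_ASPECT_SCORE = {"N": 3, "NE": 3, "NW": 3, "E": 2, "W": 2, "S": 1, "SW": 1, "SE": 1}


def aspect_sector(deg: np.ndarray) -> np.ndarray:
    """Compass sector index (0=N ... 7=NW) for bearings in degrees."""
    return (np.floor(((np.asarray(deg, dtype=float) % 360.0) + 22.5) / 45.0).astype(int)) % 8


def aspect_to_score(layer: GridLayer, *, flat_score: int = 3) -> GridLayer:
    """Score terrain aspect: poleward (N/NE/NW) 3, E/W 2, equatorward 1.

    Flat cells (flagged -1, direction undefined) default to suitable on
    the rationale that flat ground imposes no aspect penalty.
    """
    v = np.asarray(layer.values, dtype=float)
    valid = layer.valid_mask()
    flat = valid & (v < 0)
    sector = aspect_sector(np.where(v < 0, 0.0, v))
    score_lut = np.array([_ASPECT_SCORE[s] for s in _SECTORS], dtype=np.int16)
    scores = score_lut[sector]
    scores[flat] = flat_score
    return _score_output(layer, scores, valid)


def reclassify(layer: GridLayer, spec: CriterionSpec, legend: dict[int, str] | None = None) -> GridLayer:
    """Dispatch on the spec kind (continuous / categorical / aspect)."""
    if spec.kind == "continuous":
        return reclassify_continuous(layer, spec)
    if spec.kind == "categorical":
        if legend is None:
            raise ReclassifyError(f"{spec.name}: categorical layer needs a legend")
        return reclassify_categorical(layer, spec, legend)
    if spec.kind == "aspect":
        return aspect_to_score(layer)
    raise ReclassifyError(f"{spec.name}: unknown criterion kind {spec.kind!r}")


# -- Ethiopian agro-ecological zones -----------------------------------

#: Traditional elevation belts; code -> (name, lower bound inclusive, upper exclusive)
AGRO_ZONES: dict[int, tuple[str, float, float]] = {
    1: ("Berha", -math.inf, 500.0),
    2: ("Kolla", 500.0, 1500.0),
    3: ("Weyina Dega", 1500.0, 2300.0),
    4: ("Dega", 2300.0, 3200.0),
    5: ("Wurch", 3200.0, 3700.0),
    6: ("High Wurch", 3700.0, math.inf),
}


def classify_agroecology(dem: GridLayer) -> GridLayer:
    """Classify a DEM (m a.s.l.) into the six traditional elevation belts.

    The bands partition the whole real line, so every finite elevation
    receives exactly one zone code.
    """
    v = np.asarray(dem.values, dtype=float)
    valid = dem.valid_mask()
    codes = np.zeros(v.shape, dtype=np.int16)
    for code, (_, lo, hi) in AGRO_ZONES.items():
        codes[valid & (v >= lo) & (v < hi)] = code
    out = np.where(valid, codes, SCORE_NODATA).astype(np.uint8)
    return dem.like(out, nodata=SCORE_NODATA, units="agroecology zone")
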