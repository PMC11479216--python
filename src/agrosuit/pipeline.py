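"""End-to-end suitability pipeline: weights -> scores -> overlay -> areas."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .ahp import HierarchyModel, compose_weights, hierarchy_report
from .criteria import load_criteria, reclassify
from .grid import GridLayer
from .overlay import (
    DEFAULT_BREAKS,
    SuitabilityResult,
    classify_suitability,
    tabulate_areas,
    weighted_overlay,
)

log = logging.getLogger("agrosuit")

__all__ = ["RunConfig", "run_pipeline", "run_suitability"]


@dataclass
class RunConfig:
    """File-based run description for the umbrella CLI."""

    layer_paths: dict[str, str]
    hierarchy_path: str
    criteria_path: str | None = None
    legends: dict[str, dict[int, str]] = field(default_factory=dict)
    breaks: tuple[float, float] = DEFAULT_BREAKS
    cr_threshold: float = 0.1
    seed: int = 0
    out_dir: str = "results"


def run_suitability(
    layers: dict[str, GridLayer],
    hierarchy: HierarchyModel,
    *,
    legends: dict[str, dict[int, str]] | None = None,
    criteria_specs=None,
    breaks: tuple[float, float] = DEFAULT_BREAKS,
    cr_threshold: float = 0.1,
) -> tuple[SuitabilityResult, dict]:
    """In-memory pipeline core shared by CLI, scripts and tests.

    Reclassifies every input layer with its criterion rules, overlays the
    scores with the composed hierarchy weights, classifies and tabulates.
    Returns the suitability result and a JSON-able run report.
    """
    t0 = time.perf_counter()
    legends = legends or {}
    specs = criteria_specs or load_criteria()
    weights = compose_weights(hierarchy, cr_threshold=cr_threshold)
    missing = set(weights) - set(layers)
    extra = set(layers) - set(weights)
    if missing or extra:
        raise ValueError(
            f"layer stack does not match hierarchy leaves: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    scores: dict[str, GridLayer] = {}
    for name in weights:
        if name not in specs:
            raise ValueError(f"no criterion rules for layer {name!r}")
        scores[name] = reclassify(layers[name], specs[name], legends.get(name))
        log.info("reclassified %s", name)
    pacp = weighted_overlay(scores, weights)
    classes = classify_suitability(pacp, breaks)
    table = tabulate_areas(classes)
    report = {
        "software": f"agrosuit {__version__}",
        "weights": {k: float(v) for k, v in weights.items()},
        "consistency": {
            name: {
                "lambda_max": res.lambda_max,
                "ci": res.ci,
                "cr": res.cr,
                "ri": res.ri_used,
                "weights": res.as_dict(),
            }
            for name, res in hierarchy_report(hierarchy).items()
        },
        "breaks": list(breaks),
        "areas": table.to_dict(orient="records"),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    result = SuitabilityResult(pacp=pacp, classes=classes, area_table=table, breaks=breaks)
    return result, report


def run_pipeline(config: RunConfig) -> tuple[SuitabilityResult, dict]:
    """File-based pipeline: read inputs, run, write all artifacts."""
    from . import io as aio

    layers = {name: aio.read_grid(path) for name, path in config.layer_paths.items()}
    hierarchy = aio.read_hierarchy_yaml(config.hierarchy_path)
    specs = load_criteria(config.criteria_path)
    result, report = run_suitability(
        layers,
        hierarchy,
        legends=config.legends,
        criteria_specs=specs,
        breaks=config.breaks,
        cr_threshold=config.cr_threshold,
    )
    report["seed"] = config.seed
    os.makedirs(config.out_dir, exist_ok=True)
    aio.write_grid(result.pacp, os.path.join(config.out_dir, "pacp.asc"))
    aio.write_grid(result.classes, os.path.join(config.out_dir, "classes.asc"))
    result.area_table.to_csv(os.path.join(config.out_dir, "areas.csv"), index=False)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return result, report
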