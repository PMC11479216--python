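#!/usr/bin/env python
"""Generate the seeded synthetic study landscape.

Builds the 14-layer thematic stack (terrain, climate, soils, land cover,
access distances), the SAR backscatter scene with coffee patches, gauge
stations and ground-truth points.  Rasters go to scratch/landscape/ (they
are bulky, regenerable artifacts); a summary table of layer statistics
goes to results/landscape_summary.csv.
"""

import json
import os

import numpy as np
import pandas as pd

from agrosuit import io as aio
from agrosuit.synthetic_data import LandscapeConfig, generate_landscape

ROOT = os.path.join(os.path.dirname(__file__), "..")
SCRATCH = os.path.join(ROOT, "scratch", "landscape")
OUT = os.path.join(ROOT, "results")
SEED = 42


def main() -> None:
    os.makedirs(SCRATCH, exist_ok=True)
    os.makedirs(OUT, exist_ok=True)
    scape = generate_landscape(LandscapeConfig(seed=SEED))

    rows = []
    for name, layer in scape.layers.items():
        v = layer.values[layer.valid_mask()].astype(float)
        rows.append({"layer": name, "units": layer.units,
                     "min": round(float(v.min()), 3), "max": round(float(v.max()), 3)})
        aio.write_grid(layer, os.path.join(SCRATCH, f"{name}.asc"), fmt="%.17g")
    aio.write_grid(scape.sar_db, os.path.join(SCRATCH, "sar_db.asc"), fmt="%.17g")
    aio.write_points_csv(scape.ground_truth_points, os.path.join(SCRATCH, "coffee_points.csv"))
    aio.write_features_geojson(scape.roads, os.path.join(SCRATCH, "roads.geojson"), kind="road")
    aio.write_features_geojson(scape.rivers, os.path.join(SCRATCH, "rivers.geojson"), kind="river")
    pd.DataFrame([vars(s) for s in scape.stations]).to_csv(
        os.path.join(SCRATCH, "stations.csv"), index=False
    )
    with open(os.path.join(SCRATCH, "manifest.json"), "w") as fh:
        json.dump({"seed": SEED, "shape": list(scape.config.shape),
                   "hash": scape.content_hash()}, fh, indent=2)

    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(OUT, "landscape_summary.csv"), index=False)
    print(summary.to_string(index=False))
    lulc = scape.layers["lulc"].values
    print("\nagroforestry fraction: %.1f%%  (target 44.5%%)" % (100 * (lulc == 2).mean()))
    print("coffee patch cells: %d (%.2f km^2 at 10 m pixels)"
          % (scape.coffee_truth.sum(), scape.coffee_truth.sum() * 1e-4))
    r = np.corrcoef(scape.layers["elevation"].values.ravel(),
                    scape.layers["max_temp"].values.ravel())[0, 1]
    print("elevation-max_temp correlation: %.3f (strongly negative, as in highland climate)" % r)
    print("wrote rasters to", os.path.relpath(SCRATCH, ROOT))


if __name__ == "__main__":
    main()
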