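# Methods

## Priority derivation and consistency

Weights are derived by the column-normalisation / row-average method
(each column of the judgment matrix divided by its sum, rows averaged),
not by eigen decomposition: this is the variant whose intermediate
tables practitioners publish, and it makes desk-checking against printed
normalised matrices possible. A power-iteration principal eigenvector
(`agrosuit.ahp.eigenvector_weights`) is kept purely as a cross-check; on
every matrix in the shipped hierarchy the two methods agree within 0.01
per component.

`λ_max` is estimated as the mean over rows of `(A·w)_i / w_i` (the
"weighted sum and priority" recipe), which for reciprocal matrices is
always ≥ n, with equality iff the judgments are perfectly transitive.
`CI = (λ_max − n)/(n − 1)` and `CR = CI/RI(n)` use Saaty's random-index
table (0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49 for
n = 1…10). The RI table is injectable because published CR values are
occasionally computed with other tables; with the canonical table the
shipped hierarchy's CRs are main 0.030, climate 0.032, edaphic 0.008,
physiographic 0.001, socioeconomic 0.016 — all below the 0.1 acceptance
bound that `compose_weights` enforces (overridable with `force=True`).

Fractional judgments are accepted as `p/q` strings and parsed exactly
as rationals before float conversion, so `3/2` and `2/3` are true
reciprocals. One matrix in the shipped hierarchy (the meteorological
sub-matrix) records a single comparison asymmetrically (2 one way, 2/3
the other); because the published priorities derive from that table
verbatim, `validate_reciprocal` offers a non-strict mode that downgrades
reciprocity violations to warnings, and the fixture uses it for that one
matrix. Validation remains strict by default.

Comparisons against printed tables use half-up rounding at the printed
precision (`round_half_up`). Where a source table visibly truncates
instead (0.097 printed as 0.09), the tests compare the value with a
correspondingly widened band and say so.

## Reclassification rules

Continuous rules are ordered interval → score mappings with explicit
per-bound closure. The default is lower-closed / upper-open, and every
boundary shared by two classes is closed on the side of the *better*
class: 1600 mm rainfall scores 3 (suitable), pH 7.5 scores 2, a 30 %
slope scores 2. The shipped `criteria_coffee.yaml` encodes the Coffea
arabica requirements for all 14 criteria; unknown categorical codes fail
loudly unless a `default_score` is configured.

The shipped minimum-temperature rule keeps its source thresholds
(> 18 °C suitable) even though highland station minima rarely reach
them; on the synthetic landscape this simply yields score-2 cells, and
users with different crop tables can swap the YAML.

Terrain aspect uses eight 45° compass sectors centred on the cardinal
and intercardinal bearings (N = [337.5°, 22.5°), …). Poleward-facing
sectors (N/NE/NW) score 3, E/W 2, equatorward 1. Flat cells (gradient
below 1e-12, flagged −1) score 3 on the rationale that flat ground
imposes no aspect penalty; this is a parameter of `aspect_to_score`.

Agro-ecological zoning cuts the DEM into the six traditional Ethiopian
elevation belts (Berha < 500 m … High Wurch > 3700 m); the bands
partition the real line, so classification is total and unambiguous.

## Surfaces

* **IDW** uses power 2 and all stations (no neighbourhood cutoff — with
  a handful of gauges truncation gains nothing); both are arguments.
  Cell centres within 1e-9 m of a station return the station value
  exactly, and outputs are convex combinations of station values, hence
  never leave their range. Station lat/lon must be projected to the
  grid's planar frame by the caller; the synthetic tests use an identity
  projection.
* **Slope/aspect** use Horn's 3×3 weighted differences. Borders are
  padded by odd reflection (linear extrapolation), so affine surfaces
  keep their exact gradient everywhere including edges. Slope is
  reported in percent; aspect is the *downhill* bearing in degrees
  clockwise from north (a plane rising eastward has aspect 270°) — the
  convention the N/NE/NW-suitable rule expects.
* **Distance rasters** measure each cell centre's exact point-to-segment
  distance to the nearest feature (shapely, no raster dilation); cells
  whose footprint is clipped by a feature are clamped to 0. Centre
  distances are 1-Lipschitz across adjacent cells; at clamped cells the
  step can reach √2.5 pixels, which is the exact bound implied by the
  definition.

Average annual temperature is provided as (min + max)/2
(`mean_temperature`) for synthetic workflows; pipelines with a measured
average-temperature layer can pass it directly.

## Coffee mapping

The threshold interval is the min/max (optionally symmetric quantiles,
`trim_fraction`) of the dB values sampled at ground-truth points;
sampling is nearest-cell under the half-open footprint convention
(points on shared edges resolve right/down, top edge inclusive). The
interval is closed on both ends, so boundary values count as coffee.
Points on nodata cells are reported separately and excluded.

## Weighted overlay

PACP is accumulated layer-by-layer in sorted-name order, which makes the
result bit-reproducible and identical to a per-cell loop over the same
ordering. Nodata propagates strictly: a cell missing any criterion is
void (a silently dropped criterion would bias the score); there is no
silent reweighting. Class breaks default to equal thirds of [1, 3]
(5/3, 7/3) — the class-break rule is not fixed by any crop standard, so
it is an explicit parameter recorded in the run report. Areas are
tabulated in km² and percent of valid cells.

Accuracy helpers compute overall accuracy (trace/total) and Cohen's
kappa from a reference × predicted confusion matrix; kappa is reported
as undefined (None) when chance agreement is 1.

## Synthetic landscape

The generator emulates a Gedeo-like highland layer stack: elevation
rescaled to [1329, 3088] m, rainfall [1093.02, 1667] mm, SOM [0, 6] %,
CEC [0, 43] cmol+/kg, pH [4, 7.5], six land-cover classes at the
reference-year proportions (agroforestry 44.54 %, farmland 41.34 %,
forest 7.33 %, settlement 4.85 %, wetland 1.22 %, grassland 0.72 %), and
a SAR scene whose coffee patches lie inside the field-observed interval
[−19.034781, −10.773612] dB with background in a disjoint interval
(default [−9.5, −4] dB).

Construction: continuous fields are Gaussian-filtered white noise
(kernel width `smooth_sigma`, default 8 px) affinely rescaled to range;
categorical fields are carved from a smooth field by quantile
thresholding, which hits target proportions up to ties and produces
contiguous patches; temperatures are affine in elevation (lapse rates
0.0044 / 0.0068 °C m⁻¹ for min/max, anchored at 1515 m = 12.7 / 28 °C,
matching the gauge record) plus 0.1 °C noise, giving the strong negative
elevation–temperature correlation (< −0.9) the interpolation layers
assume. Stations sit at random cells and carry the field values there,
so IDW has exact ground truth. Six stations are generated by default
(the gauge network size; the packaged observed table has five rows).

Coffee patches are placed inside agroforestry cells (45 % of them by
default). The ground-truth sample (default 50 points) always includes
the cells holding the scene's lowest and highest coffee dB — mirroring a
field campaign that brackets the backscatter range — so the derived
min/max threshold spans every patch cell and noiseless recovery is
exact (Jaccard 1). With dB noise (`db_noise_sd`), patch values are
clipped to the coffee interval and background values away from it, so
the scene stays separable; recovery stays ≥ 0.99.

What the generator does **not** emulate: SAR speckle statistics and
incidence-angle effects, spatial autocorrelation between soil variables,
elevation-dependent rainfall, roads that follow terrain, and mixed
pixels at patch edges. Passing tests therefore demonstrate the
correctness of the pipeline's arithmetic and its recovery behaviour
under the stated noise model — not classification skill on real scenes.
Because the full highland relief range is compressed into a small grid,
synthetic slopes are much steeper than real terrain; slope scores on the
synthetic stack are dominated by the unsuitable class.

## Problem sizes and determinism

The default grid is 128×128 at 10 m, which keeps the full test suite
fast; the end-to-end check also runs once at 512×512. All randomness
flows from a single integer seed through `numpy.random.default_rng`;
identical configuration and seed give byte-identical landscapes
(SHA-256 over all arrays, features and points).

## Known limitations

* Single-CRS, single-grid world: only nearest-neighbour co-registration,
  no reprojection; callers project station/feature coordinates.
* The class-break choice for PACP is conventional, not derived; results
  should always be read together with the recorded breaks.
* Kappa/accuracy operate on user-supplied confusion matrices; the
  package does not itself build reference classifications.
* ASCII-grid I/O is plain text: compact enough for test scales, but not
  the format of choice for very large rasters.
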