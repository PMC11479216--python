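# Suitability rules for Coffea arabica, one block per thematic criterion.
# Scores: 3 = suitable, 2 = sub-suitable, 1 = unsuitable.
# Continuous intervals are lower-closed / upper-open by default; where a
# boundary is shared between two classes the rule on the better-class side
# closes it (closed_max: true), so e.g. 1600 mm rainfall scores 3 and
# pH 7.5 scores 2.
criteria:
  rainfall:
    kind: continuous
    units: mm
    rules:
      - {score: 3, min: 1600, max: 1800}
      - {score: 2, min: 1100, max: 1600}
      - {score: 2, min: 1800, max: 2000, closed_max: true}
      - {score: 1, max: 1100}
      - {score: 1, min: 2000, closed_min: false}
  avg_temp:
    kind: continuous
    units: degC
    rules:
      - {score: 3, min: 18, max: 23}
      - {score: 2, min: 15, max: 18}
      - {score: 2, min: 23, max: 26, closed_max: true}
      - {score: 1, max: 15}
      - {score: 1, min: 26, closed_min: false}
  min_temp:
    kind: continuous
    units: degC
    rules:
      - {score: 3, min: 18}
      - {score: 2, min: 10, max: 18}
      - {score: 1, max: 10}
  max_temp:
    kind: continuous
    units: degC
    rules:
      - {score: 3, max: 25}
      - {score: 2, min: 25, max: 30, closed_max: true}
      - {score: 1, min: 30, closed_min: false}
  texture:
    kind: categorical
    rules:
      - {score: 3, categories: [L, SCL, SiCL]}
      - {score: 2, categories: [CL, SL, SC, SiL, SiC]}
      - {score: 1, categories: [S, C, Si, LS]}
  ph:
    kind: continuous
    units: pH
    rules:
      - {score: 3, min: 5, max: 6.5}
      - {score: 2, min: 4.5, max: 5}
      - {score: 2, min: 6.5, max: 7.5, closed_max: true}
      - {score: 1, max: 4.5}
      - {score: 1, min: 7.5, closed_min: false}
  som:
    kind: continuous
    units: percent
    rules:
      - {score: 3, min: 3}
      - {score: 2, min: 2, max: 3}
      - {score: 1, max: 2}
  cec:
    kind: continuous
    units: cmol+/kg
    rules:
      - {score: 3, min: 25}
      - {score: 2, min: 15, max: 25}
      - {score: 1, max: 15}
  elevation:
    kind: continuous
    units: m
    rules:
      - {score: 3, min: 1400, max: 1800}
      - {score: 2, min: 900, max: 1400}
      - {score: 2, min: 1800, max: 2500, closed_max: true}
      - {score: 1, max: 900}
      - {score: 1, min: 2500, closed_min: false}
  slope:
    kind: continuous
    units: percent
    rules:
      - {score: 3, max: 12}
      - {score: 2, min: 12, max: 25, closed_max: true}
      - {score: 1, min: 25, closed_min: false}
  aspect:
    kind: aspect
    units: degrees
  lulc:
    kind: categorical
    rules:
      - {score: 3, categories: [agroforestry]}
      - {score: 2, categories: [farmland, grassland]}
      - {score: 1, categories: [forest, settlement, wetland]}
  dist_road:
    kind: continuous
    units: m
    rules:
      - {score: 3, max: 2000}
      - {score: 2, min: 2000, max: 5000, closed_max: true}
      - {score: 1, min: 5000, closed_min: false}
  dist_river:
    kind: continuous
    units: m
    rules:
      - {score: 3, max: 1000}
      - {score: 2, min: 1000, max: 5000, closed_max: true}
      - {score: 1, min: 5000, closed_min: false}
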