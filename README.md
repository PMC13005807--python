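# gridepi

Grid-based spatial epidemiology toolkit. It implements, as a tested and
reusable pipeline:

- **`gridepi.synthetic`** — a synthetic disease-registry generator: a regular
  lattice of populated 1×1 km cells grouped into contiguous administrative
  units, a categorical land-cover raster, and longitudinal case residential
  histories (one cell per year from birth to diagnosis) whose onset hazard can
  be raised or lowered inside planted circular clusters active during a chosen
  life stage. Planted structure is exact ground truth for parameter-recovery
  testing.
- **`gridepi.windows`** — life-stage exposure windows: for each case the
  representative ("most dominant") residential cell at diagnosis, in the first
  5 years after birth, in the 5 years before diagnosis, and over the whole
  birth-to-diagnosis span.
- **`gridepi.incidence`** — per-unit case counts, crude and directly
  standardised incidence per 100,000 person-years, observed-vs-expected
  differences against the national rate, quintile / top-2% display classes,
  and nativity stratification.
- **`gridepi.scan`** — a from-scratch discrete-Poisson circular spatial scan
  statistic: distance-ordered candidate windows capped by population fraction
  (default 5%) and radius (default 100 km), one-sided high- and low-risk
  scans, Monte Carlo p-values (default 999 replications), relative risks, and
  greedy non-overlapping secondary clusters.
- **`gridepi.lulc`** — 17→5 class land-cover reclassification (Urban,
  Agriculture, Forest, Open land, Lakes and streams), circular zonal
  histograms with a cell-centre rule, and group mean shares per exposure
  window and scan direction.
- **`gridepi.cartogram`** — a Dorling cartogram layout: one circle per unit
  with area proportional to population, iteratively relaxed to remove
  overlaps.
- **`gridepi.pipeline` / `gridepi.cli`** — end-to-end orchestration from a
  single YAML config with a JSON run manifest.

All I/O is plain text: CSV tables, GeoJSON vector layers, and ESRI ASCII grid
(`.asc`) rasters.

## CLI

```bash
# full pipeline from a config file
gridepi all --config demo.yaml --out-dir out/

# or stage by stage
gridepi simulate --config demo.yaml --out-dir out/
gridepi assign --cases out/cases.csv --out out/assignments.csv
gridepi incidence --assignments out/assignments.csv --grid out/grid.csv \
    --years 18 --out out/unit_incidence.csv
gridepi scan --assignments out/assignments.csv --grid out/grid.csv \
    --window first5 --direction high --replications 999 --seed 1 --out-dir out/
gridepi lulc --raster out/lulc.asc --clusters out/clusters.csv --out out/cluster_lulc.csv
gridepi cartogram --grid out/grid.csv --out out/cartogram.geojson
```

Example config:

```yaml
scenario:
  grid_nx: 30
  grid_ny: 30
  cell_size_m: 1000
  years: [2005, 2022]
  baseline_incidence: 36.0
  age_range: [0, 30]
  relocation_prob: 0.03
  n_units: 25
  urban_fraction: 0.25
  background_pop_mean: 100
  seed: 1
  planted_clusters:
    - centre: [6500, 6500]
      radius_m: 2400
      risk_multiplier: 2.0
      active_window: first5
scan:
  max_pop_fraction: 0.05
  max_radius_m: 100000
  n_replications: 999
  alpha: 0.05
```

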