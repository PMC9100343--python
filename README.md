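# recpot

Spatial multi-criteria evaluation of nature-based recreation potential.

`recpot` implements a reusable raster pipeline for building an integrated
recreation-potential index from 15 co-registered indicator layers:

- **Weighting** — subjective weights from pairwise-comparison (judgment)
  matrices via the principal eigenvector with Saaty's consistency test
  (CR < 0.1); objective entropy weights from the indicator value
  distributions; and their normalized geometric-mean fusion.
- **Overlay** — polarity-aware min-max standardization (larger is always
  better after standardization) and a weighted-sum index in [0, 1], with
  per-epoch or pooled (cross-epoch) standardization ranges.
- **Classification** — five ordinal potential levels, either by fixed
  breakpoints or by a geometric-interval fit (class widths form a geometric
  series, ratio chosen to minimize within-class squared deviation).
- **Change analysis** — K×K area-flow transition matrices between epochs,
  per-level area change and growth rates, and zonal summaries (protected vs
  non-protected areas, either side of a division line).
- **Elevation response** — random point sampling, a continuity-constrained
  two-segment breakpoint regression of the index on elevation (slopes per
  1000 m), and elevation-band profiles.
- **Indicators** — Shannon land-cover diversity in a moving window and exact
  Euclidean distance-to-feature layers are computed from primary data; all
  other indicators are registered from externally supplied rasters.
- **Synthetic landscapes** — a fully seeded generator for DEMs, correlated
  indicator fields with configurable elevation loadings and a planted
  elevation threshold, categorical land cover, vector features and zones, so
  the entire pipeline is testable without any external data.

Rasters are plain-text ESRI ASCII grids (`.asc`) with a `.prj` sidecar
carrying the CRS identifier; vectors are GeoJSON; tables are CSV.

## CLI

Every stage is a subcommand taking `--config` (YAML) and `--seed`:

```sh
# generate a synthetic input bundle into ./run
recpot simulate --config examples/base.yaml --seed 1 --out run

# then, using the run.yaml written into the bundle:
recpot weights     --config run/run.yaml
recpot compute     --config run/run.yaml
recpot classify    --config run/run.yaml
recpot transitions --config run/run.yaml
recpot zones       --config run/run.yaml
recpot elevation   --config run/run.yaml --seed 1
```

A minimal config:

```yaml
run_dir: .
epochs: ["2000", "2010", "2020"]
weights: {source: bundled}          # or table:/ahp_matrix: with a CSV path
standardization: {minmax_policy: global}
classification: {mode: geometric_interval, K: 5}
elevation: {n_points: 1000, band_width_m: 50.0}
simulate: {shape: [120, 120], seed: 1}
```

`weights.source: bundled` uses the packaged reference weight table from the
Qinghai-Tibet Plateau case study (`recpot.datasets.load_qtp_weights`).

## Library example

```python
import recpot as rp
from recpot.datasets import qtp_weight_set

land = rp.generate_landscape(rp.LandscapeConfig(shape=(120, 120), seed=1))
mm = rp.pooled_minmax(land.stacks.values())
w = rp.combine_weights(qtp_weight_set("ahp"), rp.entropy_weights(land.stacks["2000"]))
pm = rp.compute_inrpi(land.stacks["2000"], w, minmax_policy="global", minmax=mm)
cm = rp.classify(pm, mode="fixed", K=5, fixed_breaks=(0.31, 0.37, 0.46, 0.61))
pairs = rp.sample_points(pm, land.dem, n=1000, seed=1)
fit = rp.fit_breakpoint(pairs)
print(pm.mean(), fit.breakpoint_m, fit.slope_post)
```
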