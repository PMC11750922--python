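# filagrow

Growth quantification of filamentous cyanobacteria cultivated in
parallel-bore microcapillary strips, from micrograph series to
size-group growth rates.

The pipeline:

1. **calibration** — cell morphometry constants (mean cell length
   1.8 µm, width 3.9 µm, projected area 6.844 µm²) and the two
   conversions: filament area → fractional cell count
   (`n = A_filament / A_cell`) and cell count → filament length
   (`L = n × L_cell`).
2. **imaging** — detects the capillary lanes from the cross-lane
   intensity profile and segments filaments per lane (Otsu threshold
   with a robust fallback for sparse foreground, 8-connected
   components, µm²-calibrated areas).
3. **tracking** — re-identifies each filament across weekly timepoints
   by per-lane optimal assignment on centroid distance, gated by a
   maximum shift (filaments are static) and maximum apparent shrinkage
   (filaments only grow); computes per-interval cell increments.
4. **growth_stats** — bins filaments by initial cell number
   (0–50 / 50–100 / 100–150), fits ordinary least squares of group-mean
   cell number vs day (the rate of increase of population, dN/dt),
   normalises by mean population size, and tests group differences with
   one-way ANOVA plus pairwise pooled-variance t-tests (α = 0.05,
   compact letter display).
5. **synthetic** — generates micrograph series with exact ground truth:
   static filaments in 10 lanes of 206 µm, apical growth following a
   per-group weekly increment schedule, rendering with PSF blur and
   Gaussian noise.
6. **pipeline / cli** — orchestration, CSV/JSON artifacts, and a
   `fit-tables` mode that fits the packaged weekly group-mean summary
   tables (`src/filagrow/data/table1.csv`, `table2.csv`).

## CLI

```sh
# full synthetic run: simulate -> segment -> track -> quantify -> stats
filagrow run --seed 42 --out results/run

# individual stages
filagrow simulate --seed 42 --out scratch/sim --pixel-size 0.5
filagrow segment  --manifest scratch/sim/manifest.csv --out scratch/obs.csv
filagrow track    --observations scratch/obs.csv --out scratch/trk --pixel-size 0.5
filagrow quantify --tracks scratch/trk/tracks.csv --out scratch/fits
filagrow stats    --tracks scratch/trk/tracks.csv --out scratch/fits

# fit the packaged weekly mean tables (slopes, normalized rates, increments)
filagrow fit-tables
```

Exit codes: 0 success, 2 configuration error, 3 stage error.

Real image series are accepted either via a manifest CSV
(`path,strip_id,timepoint_days,pixel_size_um`) or a directory of
`<strip>_<day>d.tif` files plus `--pixel-size` (the pixel size of real
micrographs is not known a priori and must be supplied).

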