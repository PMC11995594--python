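# cpforage

Habitat-suitability modelling for central-place foraging marine predators.

`cpforage` implements an end-to-end species-distribution-model (SDM) pipeline
for presence-only satellite telemetry of animals that must return to a fixed
terrestrial site (a rookery) between foraging trips — the situation of
lactating otariids such as northern fur seals in the eastern Bering Sea. It
combines hourly at-sea locations with a gridded weekly ocean-model archive
(bathymetry, bottom/surface temperature, depth-integrated plankton biomasses)
and produces suitability maps, core-habitat delineations, fishery-overlap
statistics, bias-corrected future projections, and extrapolation diagnostics.

The pipeline stages are:

1. **Pseudo-absences.** Presence-only tracking data need "could have gone
   there" locations. For each trip a first-order vector-autoregressive model
   is fitted to the hourly step vectors `s_t − μ = A(s_{t−1} − μ) + ε_t`,
   100 candidate tracks are simulated with the trip's own endpoints pinned,
   and candidate positions falling in the same or an adjacent grid cell as
   any presence within a six-day window are struck.
2. **Replicate datasets.** Presences and a partner candidate track are
   down-sampled to one location per day, unmatched days are dropped from
   both, and the result is an exactly 1:1 presence:absence dataset per
   habitat (shelf ≤ 200 m, basin > 200 m). Ten replicates propagate the
   uncertainty of the daily draws and partner choice.
3. **Classifier ensembles.** One random forest per replicate (500 trees,
   minimum node size 1, mtry tuned over {2, 3, 4} by trip-grouped 10-fold
   cross-validated AUC), with collinearity screening (|r| > 0.7 drops the
   static variable), scaled Gini importances, partial-dependence curves and
   temporal/spatial transfer metrics.
4. **Maps.** Weekly ensemble-mean suitability surfaces (Jul–Oct), blending
   of shelf/basin models in the bathymetric-mismatch zone, warm/cold-year
   composites, a 375-km accessibility crop, and core habitat as the top-25%
   quantile of each model's hindcast mean.
5. **Overlap and projections.** Regridding of core habitat onto a coarse
   0.25° fishery-catch grid with catch-share summaries; weekly
   climatological bias correction of projected archives; core-habitat change
   metrics (mean suitability, area, center-of-gravity distance); and ExDet
   analogue/univariate/combinatorial extrapolation classification.

A first-class synthetic-data generator (`cpforage.synth`) emulates every
input — spatially autocorrelated covariate fields over a shelf/basin
bathymetry gradient with a cold pool, central-place trips driven by an AR(1)
step process with a *known* selection function, and a catch grid — so every
stage is testable against ground truth without any downloads.

## Worked example

```python
import cpforage as cp
from cpforage.synth import depth_temperature_selection

grid = cp.GridSpec(lon0=-173.5, lat0=53.5, dlon=0.18, dlat=0.09, nlon=80, nlat=80)
env = cp.make_environment(grid, years=[2015, 2016, 2017], seed=11)

# animals that prefer 75-200 m depths and cool bottom water
trips = cp.simulate_tracks(env, animals=40, trips_per_animal=3,
                           selection=depth_temperature_selection(), seed=11)
reps = cp.build_replicates(trips, env, n_replicates=10, seed=11)

model = cp.HabitatModel(reps["shelf"], habitat="shelf")
results = model.fit(seed=11, temporal=False)
print(results)
print(results.importance().head(3).to_string(index=False))
```

prints

```
Habitat selection ensemble  [all / shelf]
  replicates: 10   trees: 500   mtry: [2]
  AUC_cv:   0.914 +/- 0.010
  AUC_time: nan
  variables: bathymetry, temp_bottom, temp_surface, phl, phl_avg, ncao_ncas, eup
   variable  importance       sd
 bathymetry  100.000000 0.000000
temp_bottom   38.944863 5.274928
    phl_avg   26.516878 6.025925
```

The ensemble detects the imposed selection (cross-validated AUC ≈ 0.91
against ≈ 0.5 when the same tracks are simulated with no selection), and
the two covariates that actually drove the simulated movement — bathymetry
and bottom temperature — take the top two importance ranks.
`results.partial_dependence("bathymetry")` returns per-replicate
marginal-effect curves whose smoothed ensemble is elevated inside the
selected 75–200 m band (≈ 0.61 in-band vs ≈ 0.24 outside).

From the shell, the same pipeline (through projections and extrapolation
diagnostics) runs as:

```bash
cpforage all --config examples/config-small.yaml --outdir out/
```

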