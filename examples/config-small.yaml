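# Small end-to-end configuration: runs the full pipeline in ~1 minute.
#   cpforage all --config examples/config-small.yaml --outdir out/
seed: 3
outdir: out
n_animals: 6
trips_per_animal: 2
years: [2015]
grid_nlon: 24
grid_nlat: 24
n_candidates: 10
n_replicates: 2
n_trees: 30
cv_folds: 4
mtry_grid: [2]
crop_radius_km: 500.0
future_years: [2055]
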