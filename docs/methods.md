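# Methods

This note documents the models and procedures implemented in `cpforage`,
their assumptions, the defaults and why they were chosen, and what the
synthetic study system does and does not emulate.

## The modelling problem

Satellite telemetry of central-place foragers is presence-only: we observe
where animals went, never where they declined to go. To estimate habitat
selection we manufacture pseudo-absences that answer "where could this
animal plausibly have been on this day?", pair them 1:1 with presences, and
train classifiers whose predicted probability of presence, mapped over a
gridded environmental archive, is read as habitat suitability.

Every design choice in the pseudo-absence machinery exists to make the
*null case* clean: if animals move with no environmental preference, the
classifier should find nothing (AUC ≈ 0.5). The package's acceptance tests
verify exactly that, plus the converse recovery of a known imposed
preference.

## Null track model and pseudo-absences

Each trip's hourly step vectors (lon/lat differences in degrees) get a
least-squares first-order VAR fit, `s_t − μ = A(s_{t−1} − μ) + ε_t` with
`ε_t ~ N(0, Σ)`. Candidate tracks are simulated from the fitted process
with the trip's own timestamps, started at the trip's first position, and
pinned to its last position by subtracting the closure error uniformly from
every step (`error/T` per step). Drift subtraction preserves the AR(1)
second-order structure up to O(1/T) and is exactly testable; mean-speed
resemblance is enforced by re-simulating candidates whose mean step length
falls outside [0.5, 2] times the trip's (≤ 20 retries, then flagged).

Candidate positions are struck when a presence occupies the same grid cell
or one of its 8 neighbours (queen adjacency — conservative) within ±6 days
(symmetric, `|Δdate| ≤ 6`; the archive is weekly-binned, so a six-day
exclusion prevents a pseudo-absence from being an effective presence).

**Which presences feed the filter.** The filter compares candidates to the
presence data as they enter the models: one location per trip-day (a fixed
seeded draw shared by all replicates), pooled over all trips. Filtering
against every *hourly* presence was evaluated and rejected: at this study's
scale it excludes so much of the accessible region that surviving
pseudo-absences are systematically displaced off the presence cloud, and
the no-selection control rises to AUC ≈ 0.7 — the filter itself would
manufacture the signal the models are supposed to estimate.

Partner selection ranks a trip's 100 candidates by distinct surviving days
(ties to the lowest index). Replicate 1 pairs the trip with the top-ranked
candidate; later replicates walk a seeded permutation of the remaining
eligible candidates, wrapping when fewer candidates than replicates
survive. Presences and the partner track are down-sampled to one location
per day; within each habitat a trip-day is retained only when both members
fall in that habitat on that date, which makes every replicate dataset
exactly 1:1 balanced by construction.

## Classifier ensembles

One random forest per replicate dataset: 500 trees, minimum node size 1,
`mtry ∈ {2, 3, 4}` tuned by pooled out-of-fold AUC over trip-grouped
10-fold cross-validation (a presence row and its paired pseudo-absence
share a trip id and therefore a fold — the metric measures transfer to
unseen trips). Pooled out-of-fold AUC (one AUC over all held-out
predictions) is used rather than a mean of per-fold AUCs; it is robust when
folds are small. AUC is the Mann–Whitney statistic with ties counted 0.5.
Fold balancing is greedy (largest trip first into the smallest fold), which
bounds the fold-size spread by the largest trip.

Collinearity is screened once per habitat on the pooled replicates: for any
covariate pair with |Pearson r| > 0.7 the static variable loses to the
dynamic one (bathymetry loses to bottom temperature — the dynamic variable
carries forecast skill), otherwise the later-listed variable is dropped.
Gini importances are rescaled per replicate to [0, 100] (all-equal
importances map to 50 — the degenerate case has no ranking information) and
averaged over replicates. Partial dependence evaluates the ensemble mean
prediction with one covariate pinned to each of 50 quantile-spaced values;
a lowess smooth (span 0.75) summarizes the replicate curves.

## Surfaces, core habitat, overlap

Weekly suitability surfaces are replicate-mean predicted probabilities per
cell; the shelf model predicts shelf cells plus the bathymetric-mismatch
zone, the basin model basin cells, and mismatch cells take the two-model
average. Surfaces average over Jul–Oct weeks (weeks 27–44) and years (all,
or warm/cold year lists), are cropped to a 375-km accessibility circle, and
core habitat is `value ≥ τ` with `τ` the 75th percentile (linear
interpolation) of the model's cropped hindcast mean; mismatch cells are
judged against the mean of the shelf and basin thresholds. The quantile is
computed after cropping — core habitat is defined within the accessible
domain. Cell areas use the spherical quadrilateral formula
`R² · Δλ · (sin φ₂ − sin φ₁)` with R = 6371 km.

Fishery overlap regrids the fine binary core map (core for ≥ 1 complex)
onto the 0.25° catch grid by averaging fine-cell indicators whose centers
fall in each coarse cell (center-containment; unbiased when fine ≪ coarse).
Reported are the share of total catch in coarse cells with any core
habitat, and the share of core area lying in fished (catch > 0) cells.

## Projections, bias correction, extrapolation

Projected archives are corrected per variable, cell and week-of-year by the
additive offset `mean_hindcast(window) − mean_forecast(window)` over a
shared historical window, applied to the whole series; biomasses are
floored at zero afterwards and the yearly Apr–Jul phytoplankton mean is
rebuilt from the corrected weekly fields. Additive offsets are used for
temperatures *and* biomasses; a ratio scheme for biomass is a defensible
alternative (near-zero baselines make additive corrections produce zeros)
and the floor count is logged so the magnitude of that artifact is visible.

Future suitability reuses the hindcast machinery and the *hindcast*
thresholds. Change metrics per model: mean suitability over core cells,
core area, and the haversine distance from the rookery to the
suitability-weighted center of gravity of core habitat.

ExDet classifies projected conditions against the pooled Jul–Oct hindcast
reference sample: NT1 sums range-scaled univariate exceedances (< 0 ⇒
univariate novelty); NT2 is the Mahalanobis distance squared divided by the
maximum reference distance (> 1 with NT1 = 0 ⇒ combinatorial novelty;
otherwise analogue). The most-influential covariate is the variable with
the most negative NT1 term, or — for combinatorial points — the variable
whose removal most reduces the Mahalanobis distance (leave-one-variable-out
recomputation). A pooled multi-year reference is used rather than per-week
references. Variables whose novelty is an artifact of near-zero
bias-corrected biomasses can be excluded from class summaries by name.

## The synthetic study system

The generator emulates a regional shelf/basin sea with a weekly-averaged
biophysical archive, so that the statistical structure is known:

* **Bathymetry**: monotone west–east profile from 3000 m (basin) to 20 m
  (inner shelf); the "true" shelf is two columns wider than the model
  shelf, and the difference is the bathymetric-mismatch mask.
* **Bottom temperature**: latitude-driven on the shelf with a contiguous
  < 2 °C cold-pool patch at mid-shelf depths 40–100 m, blending into a
  depth-driven basin profile. This makes bathymetry and bottom temperature
  strongly correlated only in the basin, where the collinearity screen
  drops bathymetry — the screening path is exercised, not just coded.
* **Plankton biomasses**: a mid-shelf spring phytoplankton bloom that
  shifts to the outer shelf in summer (so the Apr–Jul mean and the
  late-summer weekly fields carry distinct spatial patterns), a smooth
  copepod gradient, and swarm-dominated euphausiids (weak shelf-break bump
  under strong patchy noise). The noise levels are deliberately high:
  coupled biogeochemical models have limited skill for these variables, and
  a generator whose biology is as clean as its physics would overstate what
  the real pipeline can attribute to biomass covariates.
* **Noise**: per-field kernel-smoothed white noise (Gaussian, 3-cell
  smoothing length), keyed by (seed, variable, year, week) so archives
  agree bit-for-bit on shared bins; plus per-(variable, year) offsets for
  interannual variation.
* **Movement**: hourly AR(1) steps (mean step 5.5 km/h, AR coefficient
  0.9), trip durations ~ N(6.6 d, 2.4 d) truncated at 1 d, trips sequential
  per animal with 12–60 h ashore; the 80×80 grid at 0.18° × 0.09° (~11 km
  cells) lets the resulting foraging ranges (median max distance ~150 km,
  95% ~330 km) sit inside the domain. At selection strength 0 the track
  generator *is* the null pseudo-absence generator (free AR(1) plus drift
  subtraction). With selection, each hourly step is chosen among candidate
  proposals weighted by the preference function at the proposed position;
  half the proposals redraw their heading uniformly (the AR innovation
  alone spreads proposals by ~2 km against ~11 km cells — too little for
  cell-scale selection to act on), and a homing drift
  `(rookery − x)/steps remaining` closes the bridge, with the small
  residual removed by drift subtraction. The default rookery sits on the
  75-m isobath.

What the generator does **not** emulate: ocean dynamics (advection, eddies,
fronts, sea ice), observation error in locations (tracks are exact), state-
space filtering of raw fixes, multiple rookery complexes with distinct
preferences (one complex by default), and migration trips. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and
well-calibrated under known selection structure — not that any particular
real-world covariate relationship is true.

## Problem sizes and numerical choices

The acceptance experiments use 40 animals × 3 trips over 3 years (~120
trips, ~900–1500 rows per shelf replicate), 100 candidate tracks per trip,
10 replicates, and the full 500-tree forests with mtry tuned over {2, 3, 4}
— the fixed analysis constants at a desk-scale study size. Quantiles use
linear interpolation between order statistics. The innovation covariance of
a degenerate (zero-variance) trip is floored at 1e-12; a fitted VAR with
spectral radius ≥ 1 is rescaled to 0.99. Singular ExDet reference
covariances are ridge-regularized with ε = 1e-8 · trace/p. All randomness
derives from one master seed through named substreams (CRC-keyed), so each
stage is independently reproducible and derived seeds stay below 2³¹.

## Known limitations

* The exclusion filter inevitably correlates pseudo-absence positions with
  presence density at cell scale; the daily-pool design keeps the effect
  below detection at this study's scale (null AUC ≈ 0.55) but it is not
  exactly zero, and it will grow with tracking density.
* Temporal-transfer AUC is confounded with space when years and areas are
  sampled jointly, as in the real sampling designs this emulates.
* VAR fitting in degrees absorbs the lon/lat anisotropy into A and Σ; at
  mid-latitudes over trip scales this is benign, but the fitted parameters
  are not physically interpretable as isotropic speeds.
* Endpoint pinning by drift subtraction slightly shrinks step variance
  (O(1/T)); both presences (at strength 0) and pseudo-absences share the
  distortion, so the null comparison is unaffected.
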