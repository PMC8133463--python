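# Methods

This note documents the models, the synthetic study world, the numerical
choices, and the limits of what the test suite shows. Everything empirical
mentioned here is computed by the tests or by `scripts/acceptance.py`.

## The modelling problem

A climate-envelope SDM relates point records of a species (presences,
absences, background pseudo-absences) to gridded climatic covariates and
projects the fitted probability of occurrence over space. The workflow
implemented here targets species whose range is limited from above by heat
and dry-season rainfall: occurrence collapses once maximum temperature of
the warmest month or precipitation of the driest quarter exceeds a
threshold. Five covariates are used throughout: `bio_maxtemp` (°C),
`bio_tseason` (dimensionless seasonality index), `bio_trange` (°C),
`bio_pwet` (mm), `bio_pdry` (mm). Temperatures are plain °C and
precipitation plain mm; datasets that store °C×10 must be converted on
ingest.

## Data assembly

- **Presences** are used as-is.
- **Transect absences**: each walked transect without a detection
  contributes one absence at its great-circle midpoint; transects with
  detections contribute nothing (their sightings normally enter the
  presence set separately).
- **Pseudo-absences** are sampled uniformly (in lon/lat) over a rectangular
  background region, rejecting proposals within `min_dist_km`
  (default 10 km, haversine with Earth radius 6,371 km) of any presence.
  The exclusion buffer applies to presences only, not to transect
  absences. Rejection sampling aborts after 1,000 × n proposals.
- **Covariate extraction** takes the value of the grid cell containing each
  point, no interpolation; a point exactly on a cell edge belongs to the
  cell to its north-east (floor convention). Off-grid points are dropped
  with a logged count. Pseudo-absences are treated as response-0 rows in
  every algorithm; only MaxEnt reweights them (below).

## Algorithms

All five expose `fit(spec, table) → model`, `predict(model, covariates) →
p ∈ [0,1]`, and `response_curve(model, variable)`. GLM, GAM and MaxEnt
z-score covariates internally; tree methods use raw values. Defaults
(overridable per `AlgorithmSpec`):

- **GLM** — binomial GLM with linear + quadratic terms per covariate
  (statsmodels IRLS). No tuning parameters.
- **GAM** — binomial additive model, cubic B-spline basis with `df = 6` per
  covariate and penalty `alpha = 0.01` (statsmodels `GLMGam`). The light
  penalty is deliberate: with thousands of rows, a heavy penalty
  oversmooths threshold-shaped responses and shifts the apparent decline
  several °C toward the cold side. Prediction clips inputs to the training
  range before basis evaluation (B-splines are undefined beyond their
  knots), i.e. constant extrapolation at the range edges.
- **MAXENT** — the penalised-regression form of maximum entropy: an
  L1-regularised logistic regression (`C = 1.0`, liblinear) of presences
  against the zero-response rows, with background weights scaled so total
  background weight equals total presence weight. Features per covariate:
  linear plus forward/reverse hinges at `n_hinge = 6` interior quantile
  knots. A quadratic feature is available (`use_quadratic`) but off by
  default: with hinges present, an unconstrained quadratic centred on the
  background mean systematically distorts the cold limb of
  threshold-shaped responses under L1 selection, which we verified by
  inspecting fitted coefficients; hinge feature sets are standard MaxEnt
  practice and already provide smooth curvature.
- **BRT** — `GradientBoostingClassifier`, depth 3, learning rate 0.01, up
  to 1,000 trees with the count chosen by an internal 20% holdout
  (`n_iter_no_change = 20`).
- **RF** — `RandomForestClassifier`, 500 trees, probability = vote
  fraction.

Degenerate inputs: a single-class response raises a degenerate-fit error;
constant covariates are dropped from smooth/linear terms and, if all
covariates are constant, every algorithm reduces to the base-rate constant
prediction. Stochastic fitters (MaxEnt, BRT, RF) are seeded from the spec;
identical spec + data + seed gives identical predictions.

**Response curves** vary one covariate over its training range with the
other four held at training means. The summary statistic used in
parameter-recovery checks is the half-maximum crossing: the covariate value
where the declining limb first falls to half the curve's maximum (linear
interpolation between grid points).

## Evaluation

- **Spatial folds.** Records — presences, transect absences and
  pseudo-absences alike — are assigned to k equal 360°/k sectors by bearing
  from the presence centroid (k = 5 by default; sector 0 starts due east,
  counter-clockwise, configurable offset so sensitivity to the arbitrary
  boundary placement can be probed). A record exactly at the centre goes to
  sector 0. Pseudo-absences fold by their own bearing; an always-in-training
  alternative is available via configuration.
- **Leave-one-segment-out CV.** Each model is fitted k times with one
  sector held out; held-out predictions are pooled and a single AUC is
  computed over all records (not averaged per fold). AUC is the
  Mann–Whitney concordance P(score₁ > score₀) + ½ P(tie), computed from
  midranks; the test suite checks it against brute-force pair enumeration.
- **Selection.** Algorithms with pooled CV AUC > 0.6 (configurable) advance
  to importance analysis and projection; selection happens strictly before
  importance is computed.
- **Importance.** For each covariate, the full CV is repeated with the
  covariate removed; ΔAUC = AUC_full − AUC_without. Shares ΔAUC_v/ΣΔAUC are
  reported only when the sum is positive; raw deltas are always kept
  (individual deltas may be slightly negative by sampling noise).
- **Max-kappa threshold.** Candidates are every distinct predicted value
  plus 0 and 1; binarisation is `p ≥ t`; Cohen's kappa
  (p_o − p_e)/(1 − p_e) is maximised with ties broken toward the smallest
  threshold. The search is implemented with sorted-array cumulative counts
  and verified against exhaustive search.

## Projection and the scenario table

Selected algorithms are refitted on all data. Each algorithm's threshold is
the max-kappa threshold of its current-conditions predictions at the
training points, and that same threshold is applied to every future
scenario (threshold transfer is asserted in the table builder). Future
grids are the current grid plus per-GCM, per-band additive deltas. Suitable
area sums (r·111.32 km)²·cos(latitude of cell centre) over cells at or
above threshold; the approximation is within 0.3% of the exact spherical
cell area at low latitudes (checked against the R²Δλ(sin φ₂ − sin φ₁)
formula in the tests). No-data cells propagate through binarisation and
ensemble means. Each (RCP, year) row reports the mean, min and max area
over algorithm × GCM members and `percent_left` = round(100·mean/mean
current area, half-up); the min–max columns are per-member values.
Ensemble probability maps are plain cell-wise means across members.

## The synthetic world

The generator emulates the structure the analysis assumes, not any real
landscape:

- Region 33.17–43.67°E, 1.86–6.87°N at 0.05° resolution (~21,000 cells) —
  the background region of the motivating study at a working scale chosen
  so a full study runs in seconds to minutes; resolution is a config field.
- `bio_maxtemp` = 28 °C + 3 °C per degree of distance from the thermal core
  (38.2°E, 4.75°N) + smoothed noise (Gaussian-filtered white noise, σ = 5
  cells, sd 0.5 °C).
- `bio_pdry` = 25 mm + 25 mm per degree of anisotropic distance
  (lon × 0.7, lat × 1.4) from a dry pole displaced to (36.9°E, 5.6°N), plus
  smoothed noise of sd 10 mm, floored at 0. The displacement and the noise
  keep the two governing bands distinct (r ≈ 0.6 over the region) — two
  separately identifiable constraints, as the envelope model posits. With a
  single shared gradient the two bands are nearly collinear and
  leave-one-out importance is unidentifiable by construction.
- The other three bands are smooth nuisance fields: mild directional
  gradients plus smoothed noise, carrying no occupancy signal.
- True occupancy p = logistic((T₀−T)/s_T)·logistic((P₀−P)/s_P) with
  T₀ = 33 °C, s_T = 1 °C, P₀ = 60 mm, s_P = 5 mm — soft rather than hard
  thresholds so likelihood fitters are well behaved, with transition widths
  matching the scale of the reported empirical thresholds (30–35 °C,
  50–70 mm).
- Presences (default 500) are drawn cell-weighted by occupancy and jittered
  within the cell. Transects (default 255 × 1 km) start stratified-random
  on a macro-grid so many fall outside the occupied core — a stand-in
  design, not an inference about any real survey layout; detection is
  Bernoulli(detection_prob × mean occupancy along the transect) with
  detection_prob = 0.8, which puts the expected detected fraction in the
  mid-single-digit percent range on the default world.
- Future grids add per-GCM offsets: six synthetic GCM labels around
  RCP/year mean warmings of 1.2–3.6 °C (spread ±0.75 °C), applied to the
  temperature bands, with small mixed-sign dry-season precipitation changes
  — warming, not rainfall, drives the projected declines.

Every generator output is a pure function of (config, seed); the pipeline
fans one global seed into per-stage seeds via `numpy.random.SeedSequence`.

## What the tests do and do not show

Passing tests show the machinery is correct and that, under the generator's
assumptions (additive-on-logit threshold responses, spatially smooth
covariates, uniform background sampling, perfect detection of presences at
their true locations), the protocol recovers the generating thresholds
(half-maximum crossings within ±2 °C of T₀ for GLM, GAM and MaxEnt at 500
presences) and ranks the two governing covariates first. They do not show
robustness to observation bias, spatial sampling artefacts, covariate
measurement error, non-additive interactions, or dispersal limits — none of
which the generator emulates. Projected areas are potential climatic range
only: no habitat masking, land use, or population processes.

## Known limitations

- The radial-sector CV assumes a roughly star-shaped study region around
  the presence centroid; pathological geometries can produce empty or
  single-class sectors (reported as degenerate-fold errors).
- Grid I/O uses per-band ESRI ASCII text rasters with a JSON sidecar; large
  production rasters would warrant a binary format and windowed reads.
- AUC variance is not adjusted for spatial autocorrelation; the spatial
  folds mitigate, but do not eliminate, optimism.
- The max-kappa search treats every distinct prediction as a candidate,
  which is exact but O(n log n) memory-bound for surfaces; thresholds are
  always derived at the training points, as in the source protocol.
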