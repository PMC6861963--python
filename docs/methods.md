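# Methods

This note documents the models and procedures implemented in `pm-gridsense`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic test-bed does and does not establish.

## Problem setting

Regulatory PM2.5 monitors are sparse (a couple of dozen stations for a
metropolitan core), while exposure assessment wants concentration surfaces at
fine space–time resolution.  The package estimates hourly PM2.5 on a 0.01°
lon/lat lattice by (1) matching heterogeneous data sources — station
observations, human-activity ("social sensing") data, satellite products and
meteorology — onto that common lattice, (2) training a deep belief network
(DBN) regressor on the labeled cells (cells containing a station), and
(3) predicting every remaining cell, hour by hour.

## Grid matching

All sources are reduced to per-hour rasters on one `GridSpec`: half-open
cells `[edge, edge+s)` in both axes, row 0 at the southern edge, cell centers
at `edge + s/2`, WGS84 degrees, timestamps as local hours from the study
start.  Point data are assigned by cell lookup; line data by geometric
clipping or kernel spreading; foreign-grid rasters by nearest or bilinear
resampling evaluated at destination cell centers with mask propagation
(a destination cell with no valid contributing source cell stays masked).
A labeled sample is one (station cell, hour) with the observation as label
and the feature vector drawn from the matched rasters; a sample enters a
training set only if every feature of the active variable combination is
valid at that cell-hour.

Distances (inverse-distance weights, kernel radii, buffers) use a local
equirectangular plane with km-per-degree fixed at the domain-center latitude
(111.320·cos φ₀ east–west, 110.574 north–south).  At city scale (< 1°) the
metric error is far below the 0.01° cell size.

## Features

* **PM_s** — inverse-distance-weighted (power 2, all stations, distance
  floor 10⁻⁶°) interpolation of the current hour's observations.  For
  *training* samples the target station is left out before interpolating;
  otherwise the feature equals the label (IDW is exact at sources) and any
  cross-validation becomes circular.  Prediction cells use all stations.
  The leave-one-out rule is a flag (`FeatureConfig.loo_pm_s`, on by default).
* **PM_t** — lag-weighted combination of IDW surfaces of the three preceding
  hours, weights 1/lag, missing lags dropped with weight renormalization.
  At a station cell the station's own past observation is an exact IDW hit
  and dominates its lag surface; this uses only past information, so it is
  not leakage.
* **RTCI** — per-cell sum of check-in counts per 5-minute snapshot, averaged
  over the hour's snapshots; cells with no observed point are filled by IDW
  over the non-empty cell centers.
* **TID** — kernel density of traffic lines weighted by a 6-level congestion
  index.  Lines are discretized into sub-segments of ≤ bandwidth/4; each
  sub-segment spreads (length × index) of mass through the quartic kernel
  K(d) = 3/(πh²)(1−(d/h)²)², which integrates to one, so total density mass
  equals total line mass (verified to 2% away from domain edges).  Bandwidth
  default 0.01° (one cell).  Because the geometry is static and only the
  index varies hourly, the implementation precomputes one unit-index density
  field per line and forms each hour as an index-weighted sum.
* **ROAD** — clipped in-cell road length over cell area (km/km²), exact via
  geometric intersection.
* **PS / Scen** — counts of pollution-source and clean-scenery POIs within
  1.1 km (≈ one cell) of the cell center.
* **Time** — encoded as two features, hour-of-day and day index, both
  min-max normalized with the rest; hour-only is available by dropping the
  DAY column from a combination.
* **AOT, NDVI, DEM, RH, TEM, EWS, NWS, SP, PBLH** — resampled rasters;
  NDVI is a 16-day scene series selected by half-open period, DEM static.

Two sample-set modes reflect the aerosol-coverage trade-off: `without-AOT`
keeps every station-hour and omits the AOT column; `with-AOT` includes it
and drops any record or prediction cell lacking a valid retrieval.  Since
geostationary AOT exists only in daytime and is cloud-gapped, the second
mode loses most samples and most map cells — the package defaults to
`without-AOT`.

## The DBN regressor

The regressor is a stack of three restricted Boltzmann machines (hidden
sizes 12, 24, 36) pre-trained greedily by contrastive divergence and then
unrolled into a feed-forward network — logistic-sigmoid hidden layers, linear
scalar output — fine-tuned against the mean-squared error.

Modelling choices that the underlying equations leave open:

* **Real-valued visible units, mean-field CD.**  Features are min-max
  normalized to [0,1] and treated as probabilities; the CD-1 reconstruction
  chain propagates probabilities rather than sampled binary states, making
  the update deterministic and exactly testable against a hand-coded oracle.
  A Bernoulli-sampling mode exists behind `sample_states`.  Chain length is
  configurable (`cd_steps`, default 1).
* **Labels are normalized too**, and the inverse transform is applied at
  prediction, so outputs are in μg/m³ and unbounded (the linear output layer
  can extrapolate beyond the training label range).
* **Initialization.**  RBM weights start at N(0, 0.6²) — on the order of
  1/√fan-in.  Much smaller scales leave every sigmoid in its linear regime,
  and the whole network then trains to exactly the linear-regression optimum
  and stays there; with order-one weights the CD pre-training produces
  diverse nonlinear features and measurably improves the fine-tuned model
  over random initialization of the same scale.
* **Output-layer warm start.**  Before backpropagation the linear readout is
  solved by least squares on the top RBM's activations.  Starting from
  near-zero output weights stalls training, because every hidden-layer
  gradient is proportional to them.
* **Fine-tuning.**  Default is Levenberg–Marquardt with the explicit
  Jacobian of the scalar output (the network has ≲ 2,000 weights, so JᵀJ is
  cheap to form; it is built with a symmetric rank-k BLAS update and solved
  by Cholesky with damping μ starting at 10⁻³, ×10 on rejection, ÷10 on
  acceptance).  Plain gradient descent (w ← w − η∇E) is available as
  `fine_tune_method="gradient"`.  Training stops at the error tolerance
  (10⁻⁴ in normalized units) or the iteration cap, and never returns
  parameters worse than the initial ones.
* **Determinism.**  All randomness (init, batch order, optional sampling)
  derives from the seed in `TrainConfig`; train → predict is bit-reproducible
  and the JSON model artifact is byte-deterministic (arrays stored as
  base64-encoded little-endian float64).

## Evaluation

R² = 1 − SS_res/SS_tot; RMSE in μg/m³; MPE is the mean *absolute* prediction
error (μg/m³); RPE = 100·RMSE/mean(observed) in percent.  The last two have
no universal definition; these are the dominant conventions in satellite
PM2.5 estimation and are isolated in one function.  Cross-validation splits
at the sample (station-hour) level with seeded folds of near-equal size;
both the pooled metrics (all held-out predictions scored once) and the mean
of per-fold metrics are reported, since published tables rarely say which
was used.  A station-blocked split is available as an extension flag (off by
default; sample-level splits share stations between train and validation
folds and therefore leak spatial information — a known optimistic bias of
this design).  Ablations share fold assignments so combination differences
are paired.  A main-effects linear regression and an intercept-only
predictor serve as baselines.

Map-level "mapping feedback" is supported by diagnostics per predicted
surface — spatial roughness (mean gradient magnitude), count of >3σ local
outliers, count of negative cells — but the accept/reject decision on a
variable stays with the user.  Negative predictions are reported, not
clipped (a `floor_at_zero` flag exists).

## Synthetic test-bed

Because the data feeds such studies use are proprietary, the package ships a
generator that emulates their statistical structure with known ground truth.

The true concentration field is

    PM(t, cell) = residual(t, cell)
                + 30 · T/(T+1)                  (traffic density T, saturating)
                + 30 · exp(−PBLH/500)           (boundary-layer trapping)
                + 12 · exp(−NDVI/0.3)           (vegetation scavenging)
                + 30 · exp(−(EWS²+NWS²)/2.5²)   (stagnant-air accumulation)
                + 18 · z(TEM)·z(RH)             (temperature–humidity interaction)

floored at zero, where the residual is an AR(1)-in-time (ρ = 0.7),
Gaussian-kernel-smoothed-in-space (sd 0.05°) field with mean 25 μg/m³ and
sd 4 μg/m³.  The defaults produce city-scale means around 50 μg/m³ with
hourly sd ≈ 20 μg/m³.  The wind term is even in each wind component, so it
carries no linear main effect; winds are gusty (hourly AR ρ = 0.5) and
temperature/humidity are noise-dominated, so these terms have substantial
hour-to-hour innovation that station-lag features cannot proxy.  That is
deliberate: the generator's purpose is a field whose covariate structure is
genuinely nonlinear, so that a nonlinear learner separates from a linear
baseline the way the method's motivation claims.  An independent
random-forest reference confirms the recoverable nonlinear R² share (~0.07)
is in the data, not an artifact of the DBN.

Other emulated properties: 20 stations placed uniformly (one per cell) over
a 0.5°×0.4° domain for 720 hours; observation noise N(0, 3²) μg/m³;
check-ins as Poisson counts at ~300 fixed anchor points with a three-peak
diurnal cycle at 5-minute cadence; 60 traffic polylines whose integer index
(1–6) peaks at the 08:00 and 18:00 rush hours; a 150-line four-level road
network; POIs clustered near road vertices (15% pollution sources, 15%
scenery); AOT affine in true PM plus noise, generated for 07–17 local only
(geostationary retrievals have no night product) and masked by unions of
random cloud disks trimmed to exactly the requested cloud fraction, so
missingness is spatially clustered like real cloud; smooth low-order
meteorological surfaces with diurnal cycles; a static DEM with no influence
on PM (a deliberate null covariate for ablation checks).  All randomness
flows from one root seed through named substreams.

What passing the synthetic tests does **not** show: performance on real
data.  The generator has no emission inventory, no chemistry or transport,
no station siting bias, no instrument drift, and its check-in/traffic
distributions are plausible rather than calibrated (no public description of
the real feeds' distributions exists).  The test-bed establishes that the
pipeline's machinery — matching, features, training, validation, mapping —
is correct and that the DBN recovers nonlinear structure when it is present.

## Problem sizes used in tests and the acceptance script

The default scenario (20 stations × 720 h = 14,400 labeled station-hours) is
generated in full.  The DBN-versus-linear comparison and the ablations run
10-fold cross-validation on a seeded subsample of 2,000 labeled samples with
`cd_epochs=30, max_iterations=40` (about 8 s per fold), which keeps the
median DBN−linear R² separation stable across seeds while the whole
comparison stays in the minutes range on one CPU.  The sample-set-mechanism
check uses a 30×24-cell city over 120 h with 80% cloud; the determinism
check runs the full pipeline twice on a 48-h city and compares artifact
bytes.

## Known limitations

* No map projection support beyond geographic degrees; no sub-hourly time.
* The L-M trainer materializes the n×p Jacobian; it is meant for networks of
  this size (≲ 2,000 weights), not larger architectures.
* IDW, KDA and buffer parameters (power, bandwidth, radius) are sensible
  city-scale defaults, not tuned values; all are exposed in configs.
* Station-level CV leakage via PM_s is prevented, but sample-level fold
  splitting still shares stations across folds (see above).
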