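# Methods

This note documents the models, numerical choices and limitations behind
`laketrack`, in the order data flow through the pipeline.

## Synthetic study design

The generators emulate a whole-lake biotelemetry study of a large ambush
predator in two contrasting post-mining lakes. The presets encode the
published study conditions: basins of 252 ha / 25 m and 311 ha / 75 m
maximum depth; dense macrophyte beds (60–91% cover over 0–12 m) in the
high-complexity basin versus trace vegetation (0.1–1.6% at 0–3 m) in the
low-complexity one; 15 tagged fish per lake with body lengths drawn from
the tagged-cohort summaries (means 86.3 / 78.9 cm, SDs 11.4 / 17.6,
clipped to the observed 52–115 cm range); transmitters bursting every
25 s with a pressure sensor saturating at 35 m; and 25/26 diver transects
per macrophyte survey. Where the source gives no value we fixed one
realistic choice and kept it: plant height ranges (40–200 cm dense beds,
5–60 cm sparse), a September expansion of vegetation in the sparse lake
(5–20% at 0–5 m), littoral/pelagic δ¹³C end-members of −20‰/−30‰ with
0.5‰ consumer noise, littoral reliance ~ Beta(6.6, 3.4) (mean 0.66),
ages 5–12 with von Bertalanffy growth (K = 0.25, t₀ = −0.5) anchored so
capture length is reached half a year after the last annulus, and a
biological intercept c = 3.5 cm for scale proportionality.

### Basin geometry

A lake is a radially symmetric bowl, depth(r) = Z_max·(1 − (r/R)^1.7)
with ±5% seeded smooth relief, rasterized at 10 m; the shoreline is the
circle of radius R = √(area/π). This is deliberately schematic: it
supports every downstream spatial operation (nearest-cell bottom lookup,
shoreline truncation of kernel densities, boundary filtering) without
pretending to reproduce real hypsography.

### Movement

The source describes two foraging modes but no generative model, so we use
the two standard minimal models of movement ecology:

- **ambush** — Ornstein–Uhlenbeck station-keeping around a home centre,
  discretized as an AR(1) with stationary SD `home_sd` (default 20 m) and
  relaxation time 30 min. Setting `home_sd = 0` degenerates to a fish
  parked at its home centre.
- **cruise** — correlated random walk: wrapped-normal heading increments
  (SD 0.25 rad per 25-s step), lognormal per-step speeds with mean
  `speed` (default 0.3 m s⁻¹, CV 0.3), plus a two-state benthic/pelagic
  Markov switch (open-water excursions) built from geometric sojourns.

Depth follows an AR(1) pull (relaxation 15 min) toward the local bottom
minus 1 m (benthic state) or the thermocline depth (pelagic state,
default 8 m), then is clamped to [0, bottom]. Both recursions are computed
with `scipy.signal.lfilter`, so a 30-fish × 30-day cohort simulates in
about a second.

**Boundary handling.** The planar walk is generated unconstrained and the
radial coordinate folded back into the basin with a triangle-wave map —
a reflective boundary that preserves path continuity and vectorizes.
The fold compresses tangential displacement for segments mapped from far
outside the shore, so when a cruising track presses on the boundary its
realized speed falls below nominal (≈15% in a 1 km basin at the default
persistence). Traits are computed from realized movement, so the analysis
is internally consistent; the speed calibration is verified under
open-water conditions where folding is negligible. The defaults were
chosen for the qualitative ambush/cruise contrast, not to match any
published trait magnitude.

### Observation model

One candidate transmission per burst interval; each is detected
independently (probability constant or a function of depth and time) and
carries coordinates only with `position_prob` (three receivers are needed
for a position, one for depth — hence depth-only fixes). Gaussian noise on
x, y (default 3 m) and depth (0.1 m); reported depth clamped to the 35-m
sensor ceiling. Detection defaults (0.6 detection, 0.85 positioning)
produce realistic gap structure while leaving enough day/night coverage
for the kernel home-range rule. The generators do **not** emulate
receiver-geometry-dependent error fields, multipath, thermocline-driven
detection loss, tag collisions or clock drift; passing tests therefore
demonstrate correctness of the analysis chain, not robustness to every
field pathology.

## Positioning

Filtering = duplicate collapse → shoreline buffer (50 m) → iterative
neighbour-speed test (2 m s⁻¹ against both neighbours, endpoints never
removed). The speed threshold is deliberately generous (~4× the sustained
swimming speed of a large esocid) so it only removes physically
implausible multilateration errors.

Intervals are left-closed, right-open on the UTC 900-s grid. Interpolation
uses strict inequalities for all three gating conditions (< 2 h, < 100 m,
< 2 m depth) and places filled points by linear interpolation in interval
index — identical to midpoint-time interpolation on a regular grid. Gaps
whose endpoints lack coordinates or depth are unevaluable and left open.
Both filtering and interpolation are idempotent.

Distance to bottom is computed per raw fix (bottom depth at the fix minus
sensor depth) and averaged within the interval; interpolated records fall
back to the q-position's own coordinates. Mortality flagging looks for a
terminal run (≥ 48 h) with x/y SD < 5 m and depth SD < 0.3 m — constancy
followed by renewed movement does not flag. The thresholds operationalize
what was originally a visual criterion.

## Daily traits

The kernel UD is evaluated with a fixed isotropic bandwidth (h = 50 m) at
the raster cell centres, masked to the lake and renormalized
(truncate-and-renormalize rather than a boundary-corrected kernel: simple,
conservative, and exactly testable against a dense-grid oracle). The 95%
region is the smallest set of highest-density cells reaching 0.95 of the
in-lake mass; area is cells × 100 m². Kernels are evaluated only within
5h of the data's bounding box (tail mass < 10⁻⁵), which makes the 900
KUDs of a cohort-month cheap without changing results at the reported
precision. The degenerate all-coincident-point day returns the single-cell
area (0.01 ha) by contract. The 1-D depth spread uses the same
highest-density construction with bandwidth 0.4 m on a 0.05 m grid; for a
single distinct depth it approaches the closed-form single-kernel width
2·1.96·0.4 ≈ 1.57 m.

Activity uses only pairs in adjacent intervals (900 s apart), so gaps do
not bias speeds downward; interpolated q-positions participate. The
day/night rule (civil twilight ± 1 h, midpoint decides; boundaries count
as day) gates the horizontal KUD at more-than-12 day and more-than-12
night positioned q-positions. TOW classes a q-position as open water at
distance ≥ 5 m from the bottom, the boundary value inclusive. Traits are
reported on natural scales; transforms belong to the statistics layer.

## Habitat

SCI bins are index products: ⌈height/2 cm⌉ (capped at 100) times
⌈coverage %⌉, so any presence scores at least 1 per axis and only true
absence scores 0, and the index tops out at exactly 10 000. Species within
a quadrat are aggregated before discretization (capped coverage sum;
coverage-weighted mean of species mid-heights), preserving total-cover
semantics. Permutation inference treats the transect × depth-bin quadrat
as the exchangeable unit; the lake test permutes lake labels, the
interaction test permutes period labels within lake (preserving lake main
effects) and uses the difference-of-period-changes statistic. Monte-Carlo
p-values carry the add-one correction; exhaustive enumeration is used
automatically when the label assignments are few enough.

## Trophic and growth

LR is reported unclipped with an out-of-range flag — exclusion of
anomalous individuals is an analyst decision, not automatic. No trophic
fractionation offset is applied by default (scale δ¹³C compared directly
to end-members); a configurable offset exists. End-members are summarized
by the mean (median available). "Averaging three scales" is implemented
as averaging *back-calculated lengths* per annulus (radius-averaging
would weight scales by size); the generators and the estimator form exact
inverse pairs at zero noise, which the tests exploit.

## Repeatability

The variance decomposition is the method-of-moments one-way ANOVA
estimator with the unbalanced-design n₀ correction and truncation of
negative between-group estimates at zero. This deliberately substitutes
for mixed models with ARMA residual structure: it is closed-form,
assumption-light and exactly testable (it matches ICC(1,1) from an
independent implementation). The cost is that positive residual
autocorrelation within individuals is not absorbed, which can inflate R
for strongly autocorrelated daily traits; treat pipeline R values as
descriptive. The calibration harness draws daily values from a Gaussian
random-intercept model with known ICC — at the study's design size
(15 individuals × 100 days) the estimator's bias is below 0.02 across
ICC ∈ {0.2, 0.5, 0.8}.

## Problem sizes

Unit tests run on a 20 ha / 20 m test basin. The behavioural-contrast
check uses the full study conditions (15 fish per mode, 30 days, 40
seeded replicates); the acceptance script uses 10 fish × 10 days per mode,
which is ample for the group-level contrasts it reports. All generators
and tests are seeded; identical seeds give bit-identical outputs.

## Known limitations

- The basin is circular and single-boweled; no littoral shelf, islands or
  real hypsography.
- No receiver-array geometry: positional error is homoscedastic Gaussian.
- Thermocline depth is a constant default in the movement model unless a
  per-date map is supplied.
- Repeatability ignores residual autocorrelation (see above), and the
  GAMLSS-type zero-one-inflated modelling of TOW is out of scope — TOW is
  reported as a raw daily fraction with its all-benthic/all-pelagic days
  visible as exact 0s and 1s.
- The twilight table uses the standard declination/hour-angle
  approximation without the equation of time (minutes-level error,
  irrelevant to the ± 1 h diel rule).
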