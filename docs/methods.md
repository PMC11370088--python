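# Methods

## The problem

Flying seabirds (albatrosses and petrels) are tracked with low-cost GPS
loggers whose sampling interval is a battery-life compromise: anywhere from
1 s to 1 h between fixes. Movement metrics built from successive fixes —
step length, ground speed, relative turning angle — are scale-sensitive.
Two opposing errors act on them:

* **measurement error**: at very short intervals the ~5 m positional jitter
  of each fix is large relative to the true step, so summed step lengths
  *over*estimate distance travelled;
* **interpolation error**: at long intervals the straight chord between
  fixes cuts the corners of the real flight path, so distance is
  *under*estimated — the more sinuous the flight, the worse.

`trackbias` quantifies both regimes by sub-sampling fine-scale (1 Hz)
trajectories at interval k = 1…3600 s and comparing each sub-sampled path
against a reference built from Doppler point speeds, and then measures how
the instability propagates into behavioural states inferred with a hidden
Markov model.

## Reference path and bias metrics

A flight at native interval dt (1 s, or 2 s for 2-s deployments) defines
the reference path F0. Its step distances are *not* taken from positions
but from the logger's Doppler point speed: `d0_i = point_speed_i * dt`,
with speed taken at the step's opening fix (left-Riemann convention).
Point speed is derived from the satellite carrier Doppler shift and is
essentially free of positional error, so at 1 s intervals it is an
accurate per-step distance proxy; the total `D0 = sum d0_i` is the actual
path length. The sub-sampled path F_k places fixes at exact multiples of
k from the flight start (positions linearly interpolated in lat/lon
between bracketing native fixes; a snap-to-nearest-fix option exists) and
measures steps as great-circle chords.

Metrics, per flight and interval:

* `PD_k = D_k / D0` — proportional distance. Only the portion of F0
  covered by the sub-sampled fixes enters D0, so a trailing remainder
  shorter than k cannot bias the ratio; without this the invariant
  PD ≡ 1 on unbiased geometry would fail for coarse k.
* Per sub-sampled step j, with the *window* of reference steps whose
  opening times fall in [t_j, t_{j+1}) (exactly k steps on a uniform
  reference, which makes `PE_dist = k * PE_speed` an exact identity):
  * `PE_dist_j = | sum(d0 in window) − chord_j |` (m)
  * `PE_speed_j = | mean(point speed in window) − chord_j / k |` (m/s)
  * `PE_angle_j = | mean(|reference turn| in window) − |turn at fix j| |`
    (degrees). Reference turning angles are attributed to the interior
    fix where the turn occurs; the sub-sampled turn compared against
    window j is the one at the window's opening fix. Signed
    distance/speed residuals (reference minus sub-sampled) are stored
    alongside the absolute values.

All distances are haversine on a sphere of radius 6 371 000 m and all
bearings initial great-circle bearings; relative turns are wrapped to
(−180°, 180°]. One consequence worth knowing: even a perfectly geodesic,
noise-free track has PD slightly below 1, because a chord under-measures
its arc by O((vk/2R)²) — about 3×10⁻⁶ at k = 3600 s and 15 m/s. The
package treats anything within 10⁻⁵ of 1 as exact.

PD aggregates are means ± SD over flights (one PD per flight per k); PE
aggregates pool sub-sampled points. Grouping is by flight class, bird or
species. The choice of flight-level PD aggregation (rather than pooled
points) is configurable.

### Correcting reported trip totals

A trip total logged at coarse intervals can be corrected for the
interpolation bias as `corrected = reported × (1 + f)` where `f` is the
fractional underestimate (1 − PD) of the relevant flight mode. For an
11,000 km trip at hourly fixes this gives 12,100 km with the ~10%
straight-flight bias and 15,400 km with the ~40% sinuous-flight bias.

## Path preparation

* **Cleaning** drops duplicate timestamps (first kept) and, when a land
  mask polygon is supplied, on-land fixes. No coastline is bundled or
  downloaded; the mask is a user-supplied GeoJSON polygon set.
* **Gap interpolation**: loggers intermittently stretch to 2 s intervals;
  a single midpoint fix (linear in lat, lon and point speed) restores a
  uniform 1 s series. Longer gaps are left as flight breaks. 2-s
  deployments skip this entirely and use `d0 = point_speed × 2`.
* **Flight segmentation**: non-flying periods are runs where the rolling
  mean speed over 10 s stays below 10 km/h for at least 60 s; removing
  them leaves the flights. The rolling window is centred (edges use the
  available samples) and the speed source is the Doppler point speed when
  present on every fix, positional step speed otherwise — both choices
  are configurable. Segmentation returns *all* flights; the bias analysis
  keeps those longer than 1 h (`min_flight_duration_s = 3600`).
* **Straightness index**: SI = great-circle displacement between flight
  endpoints over total path length, in [0, 1].
* **Threshold selection**: the percentage of flights with SI below t is
  computed on a 0.01 grid, smoothed with a 5-point moving average, and
  the knee taken as the grid point maximising the discrete second
  difference — the acceleration into the steep climb through the straight
  mode. Ties break toward the *higher* threshold: with several equally
  sharp rises this puts the knee at the base of the straightest (usually
  tightest) mode and leaves the spread of more sinuous flights below it;
  breaking ties low would plant the threshold under the most sinuous mode
  and classify everything as straight. An all-equal SI population returns
  that value with a degenerate-knee warning. Flights with SI above the
  threshold are "straight", the rest "sinuous".

## Stationary-logger validation

Loggers left at a fixed position record pure error: the cumulative
great-circle displacement between successive fixes versus the cumulative
point-speed-integrated distance (truth is zero for both). A Welch
two-sample t-test on the log-transformed per-logger totals (and on
per-second means) tests whether displacement error exceeds point-speed
error; zero totals trip a hard error naming the logger rather than a
silent −inf. When both arms are exactly constant the t statistic is
defined as 0 (equal means) — scipy returns NaN there.

## Behavioural states

Per sampling interval k, per-step speed (chord/k, m/s) and absolute
relative turning angle (degrees) feed a 3-state Gaussian HMM
(`hmmlearn.GaussianHMM`, diagonal covariances). Each fit runs 10 EM
restarts from k-means-initialised means on a fixed seed stream and keeps
the best log-likelihood; an SD floor of 10⁻³ (min_covar = 10⁻⁶) keeps
near-constant channels fittable. Decoding is global Viterbi. Semantic
labels follow the speed ordering of state means — rest slowest, commute
fastest, forage in between — with a recorded warning when forage does not
also have the largest mean turning angle, and speed ties broken toward
lower angle for commute. Angles enter as absolute values; a Gamma/von
Mises observation model would respect the supports better but the
Gaussian is the model whose sampling-rate sensitivity is being measured.
A fresh model is fitted at every k (per-k seeds spawned from one stream,
so the composition of the k grid never perturbs an individual fit).

Spatial stability: each k's points for a chosen state (default forage)
are projected with an azimuthal equidistant projection about the trip
centroid, a bivariate Gaussian kernel UD is estimated on one grid shared
across all k (default 200×200 cells, data extent plus 10% padding plus 3
bandwidths), with the reference bandwidth
`h_ref = 0.5 (SD_x + SD_y) n^(−1/6)` (metres). Densities are normalised
to integrate to 1 on the grid. Overlap between intervals is the volume of
intersection `VI = Σ min(UD_a, UD_b) × cell area`, computed on the full
UDs; the 50% kernel — the smallest density-threshold set holding half the
mass — is reported alongside each UD, matching how such comparisons are
usually presented.

## The synthetic generator

The generator is the package's ground truth: it integrates a per-second
speed/heading process on the sphere by direct great-circle stepping, so
generator and analysis share one distance convention and noise-free
round trips are exact (every true chord equals speed × dt). Regimes:

* `straight` — constant compass heading (commuting);
* `soar` — heading(t) = base + A·sin(2πt/T): the continuous fine-scale
  heading oscillation of dynamic soaring. The net-advance ratio tends to
  the Bessel factor J0(A), e.g. ≈ 0.74 at A = 60°;
* `circle` — constant turn rate v/r: at 1 Hz this traces a regular
  polygon with exactly known chord geometry, the closed-form test case;
* `meander` — area-restricted search: soaring legs flown out from and
  straight back to the bout's locale, keeping foraging in a compact patch
  while leg-scale speed stays intermediate;
* `rest` — ~0.3 m/s drift with random heading.

Observation noise matches the magnitudes reported for this logger class:
isotropic Gaussian positional jitter with 5 m SD, point-speed error with
0.006 m/s SD (clipped at zero), and fixes dropped with probability 0.02
(0.10 for at-sea deployments) such that every gap is exactly 2 s
(adjacent drops suppressed). Jitter is white; real GPS error is
autocorrelated over seconds-to-minutes, which is why real stationary
loggers accumulate far less false displacement per hour than a
white-noise model predicts — cumulative stationary error totals from the
generator are therefore *not* comparable to field values, though the
ordering (displacement error ≫ point-speed error) and everything built on
moving tracks are.

The standard simulated cohort is 10 "straight" and 10 sinuous flights of
2 h at 15 m/s. Both groups soar — what distinguishes a commuting flight
is a mild oscillation amplitude (35°), while the sinuous group spans
55–80° with periods 8–12 s, emulating the between-individual spread of
flight tortuosity. That spread is also what gives the SI population a
tight straight mode above a broad sinuous tail, the shape the knee rule
expects. Under these conditions the cohort's long-interval biases land
near 9% (straight) and 32% (sinuous).

The labelled foraging trip is a 24 h central-place pattern: rest, 4 h
commute out at 15 m/s, two foraging patches (6 h of ARS legs at 8 m/s
around 1 h of rest each) joined by a 1 h commute, 4 h return, rest. Patch
centres (true mid-bout positions) are returned so kernel tests have a
known geography. Every generator is a pure function of (config, seed).

## Numerical and design choices

* Canonical units: metres, seconds, m/s; km/h only at ingestion (declared
  unit) and reporting. Timestamps are UTC epoch seconds.
* Sub-sampling interpolates linearly in lat/lon — at ≤ 30 m native steps
  the planar/spherical difference is far below jitter.
* The k grid is 1…3600 s (even k only for 2-s deployments); the bundled
  pipeline default thins the grid to 27 values to keep runs quick without
  changing any per-k computation.
* One run seed fans out to per-stage streams via `numpy.random.SeedSequence`
  spawning; adding a stage never changes earlier stages' randomness, and
  identical (inputs, config, seed) give byte-identical output tables.
* Degenerate inputs fail loudly: empty paths after cleaning, missing
  point speeds (with fix indices), zero reference distance, coincident
  kernel points, all-restart HMM failures. A failed HMM at one interval
  flags that k and the stability curve continues.

## Problem sizes

Tests and the acceptance script run on: 2 h flights (7 200 fixes), a
600 s circle, 10-flight jitter cohorts, a 24 h trip (86 400 fixes),
n = 2 000 HMM series, 1 000-point kernel samples, and 150–321-cell grids
for overlap oracles. These sizes give sampling error comfortably inside
each test's tolerance while keeping the whole suite around ten seconds.

## Limitations

* White positional noise (no autocorrelation), no wind fields or
  dynamic-soaring aerodynamics, no behaviour-dependent fix loss.
* The Gaussian HMM is deliberately the common-practice model; its
  zero-inflation problem at fine k (speeds of exactly zero while resting)
  is floored, not modelled.
* Kernel UDs ignore serial autocorrelation of positions;
  autocorrelation-robust estimators are out of scope.
* The species-level mixed-effects comparison of sinuosity is out of
  scope; grouping by species is supported in the aggregation only.
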