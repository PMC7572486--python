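# Methods

`tdrforage` turns raw time-depth-recorder (TDR) traces from a
central-place foraging pinniped into per-trip measures of foraging
effort, success and efficiency, and into the model-ready table (trips x
lagged environmental covariates) that mixed-effects analyses consume.
This note documents the models and conventions each stage implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where more than one reading was
defensible.

## Data model and conventions

A deployment is a strictly increasing series of UTC epoch-second sample
times with depth in metres (positive down) at a nominal 1 or 5 s
interval, plus an optional salt-water-switch wet/dry flag. All files use
one open dialect: comma-separated text, header row, empty fields for
missing values. Missing is never coded as 0 — a trip with no benthic
dives has an *undefined* FTEI, not a zero one.

## Zero-offset correction

Pressure sensors drift, so the raw "surface" wanders away from 0 m. The
offset at time *t* is estimated as the lower `zoc_quantile` (default
0.05) of depth over a centred window of `zoc_window` seconds (default
3 h), evaluated on a coarse grid (window/60) and linearly interpolated,
then median-smoothed over window/3. Because surface intervals separate
successive dives, the lower tail of every window contains genuine surface
samples. The offset is subtracted and samples correcting below 0 m are
clamped to 0. Windows are time-based, so tags that stop recording when
dry are handled without special cases; a window longer than the
deployment degrades to a single global offset with a warning.

The estimator is exactly idempotent for constant offsets and nearly so
for slowly varying drift (residuals of a few centimetres for a 3 m ramp
over 10 days). For a random-walk drift the quantile tracks the local
lower envelope of the walk, giving a one-sided error of order the walk's
sub-window standard deviation; with a realistic 0.5 m/√day walk this
stays within ±0.5 m for >99% of dives.

## Dive detection and phases

A dive is a maximal run of samples deeper than `dive_threshold` (5 m, the
conventional cut excluding surface activity and sensor-resolution
differences). At 1 Hz, single-sample runs are dropped as spikes; at 5 s
they are kept. Dive duration is counted as one sampling interval per
sample run (so a single-sample dive has duration one interval).

The bottom phase spans the first to the last sample deeper than
`bottom_fraction` x maximum depth (default 0.8, the conventional
square-dive bottom definition; configurable). Descent distance *d* and
ascent distance *a* are measured from the boundary samples' depths — the
0–5 m transit is unobserved by a threshold detector, and extrapolating it
would invent data. The `dive_boundary="extended"` option instead includes
one flanking sub-threshold sample per side, approximating a
surface-to-surface convention. Descent rate is r = d / descent-duration
(m/s). Dives with fewer than 3 samples have undefined phases; they are
flagged, keep an index of 0, and are excluded from rate-based indices
while still counting toward dive numbers and PBD.

Note one geometric consequence of the 0.8 rule: a pure V-dive still
accrues a "bottom" equal to the 0.8–1.0-depth shoulders, about 20% of its
transit time. That is inherent to any depth-fraction definition and is
what keeps the weighted index of V-dives small without being zero.

## Trip and haul-out segmentation

Wet/dry intervals come from the flag, or — for tags that record only when
wet — from recording gaps longer than twice the nominal interval. Dry
spells shorter than 10 min are folded back into the surrounding wet
period (salt-water switches dry out during surface rafting); dry spells
of >= 10 min are haul-outs. Wet periods of >= 6 h containing at least one
dive are candidate foraging trips.

The published trip definition ("at least one benthic dive") references a
classification that is itself performed per trip — a circularity resolved
by a two-pass procedure: candidates are formed first, classified, then
finalised (candidates without a benthic dive are rejected). Trips
truncated by the deployment edges are flagged `partial` and excluded from
duration statistics by default. Every dive must fall inside exactly one
wet interval; violations are consistency errors, not warnings.

## Benthic/pelagic classification

Each dive's index is `max_depth x (bottom_time / duration)` — maximum
depth weighted by the proportion of the dive spent at the bottom. The
multiplicative form is the minimal reading of "depth weighted by bottom
proportion" and produces the documented bimodality: square seafloor dives
score near their depth, mid-water V-dives near zero. Within a trip,
indices are normalised by the trip maximum (making the bandwidth rule
scale-free across trips over different seafloors — the reason the
classification is per trip), a Gaussian KDE (Silverman bandwidth by
default) is evaluated on a padded grid, and local maxima with prominence
>= 5% of the peak density are modes. With >= 2 modes the nadir is the
density minimum between the two most prominent modes; dives with
normalised index strictly above it are benthic. Labels are therefore
monotone in the index by construction.

Fallbacks: trips with fewer than `min_dives_for_kde` (10) dives,
unimodal densities, or degenerate (identical) indices are labelled
all-benthic — the species' predominant mode (~78% of dives) — and the
fallback is recorded in the audit table so downstream users can filter.

## Capture probability and trip indices

For benthic dive *i* with descent rate r_i (m/s), the probability of prey
capture is the logistic

    p_i = exp(4.67 r_i − 6.06) / (1 + exp(4.67 r_i − 6.06)),

with coefficients estimated for Australian fur seals from animal-borne
video validation. The model was validated on benthic dives only, so p_i
is computed only for them. (The source labels the −6.06 intercept "dive
duration" while its printed expression contains only descent rate; the
expression as printed is what is implemented.)

Per foraging trip, over its benthic dives with durations t_i in hours:

* effort: benthic dive rate `b = Σ(d_i + a_i) / Σ t_i` (m/h);
* success: `FTSI = Σ p_i / Σ t_i` (expected captures per hour of benthic
  diving; the hours convention is declared, not inherited);
* efficiency: `FTEI = Σ p_i / b` (captures per unit vertical effort);

plus PBD (proportion of dives benthic), the proportion of at-sea time
spent diving, and the dive count N. `dive_rate_denominator="trip_time"`
divides b by the whole trip duration instead of summed dive time — an
alternative reading under which typical values fall near 10^3 m/h rather
than ~2x10^3. A pairwise-correlation audit of the three building blocks
(Σ(d+a), Σp, Σt across trips) is provided because the indices share
terms.

## Environmental covariates

Monthly series are z-scored per variable over the full study period (the
literal reading of "standardised monthly means"; removal of the monthly
climatology is available via `method="anomaly"`). Local variables enter
as austral winter (Jun–Aug) means of the current year and spring
(Sep–Nov) means lagged 1 and 2 years — prey spawn in spring and recruit
into the diet with a delay; large-scale indices (SOI, SAM, IOD) enter as
annual means at lags 0, 1 and 2. A season with any missing month is
missing, and rows with missing lags are flagged, never zero-filled.
Trips join by the calendar year of their start (trips span days, never
years, at these deployment lengths). Fitting the LME/GAMM models
themselves is deliberately out of scope: the pipeline ends at the
model-ready table.

## The synthetic-data generator

`simulate_deployment` emulates the study conditions: alternating
haul-outs (clipped-normal, mean 36 h) and foraging trips (lognormal,
mean 64.8 h ≈ 2.7 days, clipped to 6 h–10 days); per-trip seafloor depth
uniform on 28–102 m (the benthic modal-depth range of the study shelf),
constant within a trip; within trips, [exponential surface interval,
dive] cycles, each dive benthic with probability 0.78. Benthic dives are
trapezoids to the seafloor with drawn descent/ascent rates
(clipped-normal, 1.4 ± 0.25 m/s on [0.6, 2.2]) and a bottom occupying
~45% of the dive (lognormal jitter, mean one); pelagic dives are
V-profiles to ~40% of the seafloor depth (uniform per-dive scatter,
floored at 9 m) with ~5% bottom fraction. The default surface interval
(208 s) makes the renewal rate 86400/E[cycle] equal ~244.5 dives per
at-sea day; the same expectations give ~2.4 min mean dives and ~39% of
at-sea time diving. `SimConfig.expected_*` computes these analytically
(including the E[1/r] correction for rate draws and the threshold-transit
deduction for detected durations), and parameter-recovery tests compare
simulations against those expectations, not against hand-picked numbers.

Phase vertices are snapped to the sampling grid, so true maximum depths
are attained exactly at a sample and phase boundaries, rates and
threshold-crossing times are analytically known — that is what makes
"exact max depth" and "±1 sample boundary" oracle tests meaningful.
Ground truth records dive boundaries at the 5 m crossings (what a
threshold detector can recover) alongside the true surface departures.
Sensor artefacts are applied last: none/linear/random-walk zero-offset
drift (the random walk is scaled to a given standard deviation after one
day) and i.i.d. Gaussian depth noise; the drift curve is stored in the
truth bundle. All randomness flows from one seed, with per-individual
substreams at fixed offsets.

What the generator does **not** emulate — and hence what passing tests do
not establish about field data: depth-sensor quantisation and spike
artefacts beyond Gaussian noise; behavioural structure (bout clustering,
diel cycles, wiggles/steps within dives, drift dives); horizontal
movement; seafloor relief within a trip; and any environmental forcing of
behaviour. Classifier-recovery results in particular are upper bounds:
simulated benthic and pelagic index clusters are cleanly separated,
whereas real distributions overlap.

## Numerical choices and degenerate inputs

Quantiles via `numpy.quantile` (linear interpolation); KDE via
`scipy.stats.gaussian_kde`; mode finding via `scipy.signal.find_peaks`
with prominence thresholding on a grid padded beyond [0, 1] so boundary
modes are interior. Ties at the nadir go to pelagic (strict `>` for
benthic). Dive detection uses strict `>` against the threshold.
Correlations with a constant column are reported as undefined rather
than 0. Logistic evaluation uses `scipy.special.expit` (no overflow; it
saturates to exactly 1.0 in float beyond ~37 logits). Readers parse
floats with round-trip precision so write→read is an identity.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical checks have power: a 10-day 1 Hz
deployment (~2,400 dives) for detection and drift-recovery oracles; a
20-individual × 6-day 5 s cohort (~28,000 dives) for classifier and
parameter recovery; an 8-individual × 24-day cohort for the reported
study-level quantities; 24 years of monthly covariates for the lag
structure. Field-scale analyses (hundreds of deployments over decades)
use the same code paths; nothing is bounded by these sizes.

## Known limitations

* The weighted-index formula and the KDE settings are declared readings
  of a method whose source describes it only verbally; both are
  configurable, and the audit table records bandwidth, modes and nadir
  per trip so alternative settings can be compared.
* The ZOC estimator assumes the animal surfaces within every window;
  windows much shorter than typical dive cycles, or animals that stay
  submerged for hours, would bias the offset downward (deeper).
* p_i is a population-level logistic in descent rate only; it transfers
  no individual heterogeneity, and FTSI/FTEI inherit its calibration.
* Trips are wet periods, not colony round-trips: without location data a
  long thermoregulatory swim with one benthic dive counts as a trip.
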