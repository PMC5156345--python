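# Methods

This note documents the models and procedures implemented in `sealdive`,
the assumptions behind them, the simulator that provides ground truth,
and the numerical choices that matter.

## Signal model and filtering

A tag on a diving seal measures, in the body frame (X forward, Y right,
Z down; a stationary level logger reads (0, 0, +1) g):

```
a(t) = R(ψ, θ, φ)ᵀ g  +  stroking(t)·ŷ  +  bursts(t)  +  ε(t)
m(t) = R(ψ, θ, φ)ᵀ B  +  η(t)
```

with `R = Rz(ψ) Ry(θ) Rx(φ)` the body-to-NED rotation (heading ψ, pitch
θ positive nose-up, roll φ), `g` the unit gravity vector, `B` the local
magnetic field, stroking a lateral-axis oscillation in the 0.44–1.02 Hz
band, bursts broadband (> 2.64 Hz) transients from prey strikes, and
ε, η sensor noise. The three regimes are separated with order-3 digital
Butterworth filters at the 16 Hz sampling rate: low-pass 0.20 Hz
(gravity), high-pass 2.64 Hz (strike dynamics), band-pass 0.44–1.02 Hz
(stroking). All cutoffs are physical Hz. Filtering is zero-phase
(forward–backward) by default so states on different axes and the 1 Hz
depth channel stay time-aligned — the tri-axial coincidence rule is
sensitive to group delay — with a causal forward-only mode available.
Edges use reflect padding; the first/last few seconds of a record are
transient and treated as unreliable.

*Swimming effort* is the rectified band-passed lateral axis averaged
over non-overlapping 1-s blocks aligned to whole seconds. For a unit
sinusoid inside the band the steady-state value is the mean absolute
value of a sine, 2/π ≈ 0.6366, which the calibration checks reproduce.

## Prey-encounter detection

Per axis: sample SD (denominator n−1) in fixed 1-s windows of the
high-passed signal, then a centred 5-s moving SD (edges use the partial
window, minimum 3 samples), then an exact 1-D two-means split: the
partition of the sorted values minimising total within-cluster sum of
squares, found by enumerating splits with prefix sums. There is no
random initialisation, so detection is fully deterministic; WSS ties go
to the smallest high cluster. The upper cluster is the "high" state. An
event is a maximal run of seconds in which all three axes are high;
events are reported as half-open whole-second intervals — sub-second
timing is beyond the method.

Two guards handle degenerate inputs: an axis whose values are all equal
is labelled all-low, and an axis whose two states are not genuinely
distinct — between-state gap under 4 pooled within-state SDs — collapses
to all-low. The threshold sits between what a unimodal noise
distribution yields when force-split (≈ 2.5–3) and what records with
real strike transients yield (≈ 50 under the default conditions).
Clustering is performed once per deployment (not per dive) so states are
comparable across dives; a per-dive switch is not provided.

## Orientation

With unit-norm static acceleration `s`: `pitch = −arcsin(s_x)`,
`roll = atan2(s_y, s_z)`. Heading de-rotates the (0.20 Hz low-passed)
body-frame magnetic vector by roll about X then pitch about Y and takes
`atan2(−m_y, m_x)`, clockwise from magnetic north in [0, 360). Heading
is undefined (flagged) where the horizontal magnetic component falls
below 10⁻⁶ of the field norm. Sign conventions are fixed here
(nose-up positive, right-side-down positive, clockwise-from-north);
every downstream metric uses only magnitudes, steepness and circular
variances, which are convention-invariant. Angles are computed at 16 Hz
and block-circular-averaged to 1 Hz to align with depth. Circular mean
is `atan2(Σsin, Σcos)`; circular variance is `1 − R̄ ∈ [0, 1]`, with the
mean flagged undefined when `R̄ < 10⁻¹²`. No hard/soft-iron calibration
and no declination correction are applied (variances and differences of
headings are unaffected).

## Dive segmentation

**Zero-offset correction.** Pressure sensors drift slowly. Per 3-h
window, the baseline is the 10th-percentile order statistic of samples
shallower than 10 m above the running baseline, anchored at that
sample's own time — under a monotone drift the shallowest surface
readings are the earliest in the window, so anchoring at the window
centre would lag the drift — then linearly interpolated between anchors
and extrapolated at the record edges. Corrected depth is clipped at
−0.5 m (one sensor quantum). Window length and quantile are
configuration keys.

**Dives** are maximal runs of corrected depth > 15 m. Durations below
500 s (subsurface incursions) or above 1950 s (gap-merged records) are
flagged, kept for audit, excluded from analysis.

**Vertical speed** is the central difference of the 3-s moving-averaged
depth, descending positive. The smoothing suppresses the 0.5 m/s spikes
that 0.5 m depth quantization produces at 1 Hz. A 0.02 m/s deadband
classifies near-zero speeds as holding depth; it is far below any real
wiggle or step speed and far above the residual baseline slope left by
the offset correction.

**Wiggles and steps.** The sign sequence of the deadbanded speed is
compressed into descending/ascending runs. A wiggle is an adjacent
(descending, ascending) run pair — a down-then-up excursion containing
a local depth maximum — excluding the dive's own initial descent run
and terminal ascent run, so V- and U-shaped dives have no events. A
step is a maximal run of at least 5 s with speed strictly inside
(0, 0.35) m/s, the non-swimming sink-rate bound; seconds claimed by a
wiggle are unavailable to steps. The 5-s minimum and 3-s smoothing are
quantization guards: a single 0.5 m tick smeared over 3 s stays in-band
for under 5 s. Steps slower than ~0.15 m/s approach the quantization
floor and are only partially recoverable — an instrument limit, not an
algorithmic one.

**Bottom delimitation.** Qualifying events reach deeper than 75 % of
the dive's maximum depth; the bottom phase runs from the start of the
first to the end of the last qualifying event, so phase limits can
never bisect an event. Without qualifying events the first-to-last
crossing of the 75 % isobath is used and the dive flagged
`fallback_delimitation`. Phases partition the dive exactly:
descent · bottom · ascent, contiguous and ordered.

**Drift dives** (resting/digesting) are flagged when a dive contains a
≥ 200 s window with mean swimming effort below the deployment's 10th
percentile, vertical-speed SD < 0.1 m/s, and mean |vertical speed| in
0.05–0.6 m/s (a steady passive drift, not a hang). The criterion is a
reconstruction — it exists to exercise the exclusion pathway — and
every threshold is a configuration key.

## Dive-level covariates

One row per analysable dive. PEE rate = bottom events / bottom minutes
(events assigned to the phase containing their midpoint). Bottom
vertical extent = Q90 − Q10 of 1 Hz bottom depths, linear-interpolation
quantiles (stated explicitly because the extent is sensitive to the
convention). Dive efficiency = bottom/dive duration, strictly in (0,1)
by construction; violating rows are flagged, never silently dropped.
Surface speed divides the haversine distance (sphere radius
6 371 008.8 m) between the GPS fixes bracketing the dive — each must
fall in the adjacent surface interval (≤ 600 s from the dive edge) — by
the fix-to-fix elapsed time; at the few-km scale involved the
spherical-vs-ellipsoidal error is ≪ 0.5 %. Day/night comes from solar
altitude (NOAA algorithm, ~0.1° accuracy) at the dive start, at the
position linearly interpolated between fixes; altitude ≥ 0° is day,
with the threshold configurable. A companion phase table (one descent
and one ascent row per dive: duration, maximum depth, mean effort)
feeds the transit-duration model.

## Statistical models

All models consume standardized covariates (centred, unit SD; scaling
stored for back-transformation). Temporal autocorrelation is addressed
by keeping one dive in ten per individual; collinearity by a VIF < 5
screen (report, not failure). The families:

* **Bottom PEE count** (day and night fitted separately): NB2 GLM, log
  link, `log(bottom minutes)` offset with coefficient fixed at 1, so
  the modelled quantity is a rate; dispersion θ estimated by ML
  (variance μ + μ²/θ); individual identities as fixed-effect
  intercepts when several animals are present.
* **Surface speed** and **transit duration**: linear mixed models with
  a random intercept per individual; the transit model crosses phase
  type (descent/ascent) with depth and effort so the two transits get
  distinct slopes. ML is used during selection, REML for final fits.
* **Dive efficiency**: variable-dispersion beta regression — logit
  mean, log precision, Beta(μφ, (1−μ)φ) likelihood — with the
  precision submodel defaulting to the mean submodel's covariates.

Selection: backward elimination dropping, at each step, the single term
whose removal lowers AIC most (interactions are droppable before their
main effects; ties go to the later-listed term), stopping when no
removal lowers AIC; then, per retained covariate, the polynomial degree
is raised 1→2→3… while AIC keeps improving, capped at 4. Degree-1 terms
enter the design raw (the covariates are pre-standardized); higher
degrees use QR-orthogonalised polynomial bases rescaled to unit SD, so
coefficients stay on the per-SD scale. Note that AIC retains a pure
noise regressor with probability ≈ P(χ²₁ > 2) ≈ 0.16 — backward-AIC
selection recovers the true covariates essentially always but keeps an
occasional spurious one; that is a property of AIC, not of the
implementation.

Goodness of fit: for the count models, D² = 1 − residual/null deviance
(in %), with the null model = intercept + offset evaluated at the
fitted model's θ (a switch includes the individual intercepts in the
null), and per-covariate NDE = the drop in D² under single-term
deletion (these need not sum to D²). For mixed models, Nakagawa
R²m = σ²_f /(σ²_f + σ²_u + σ²_e) and R²c = (σ²_f + σ²_u)/(same), with
σ²_f the variance of the fixed-effect predictor over the data. For any
family, Pearson² = the squared correlation between link-transformed
observations and the linear predictor; zero counts get a half-count
continuity adjustment before the log (logged, configurable).
Per-individual residual autocorrelations at lags 1–20 with ±2/√n bounds
are reported, never auto-rejected.

Numerical notes: the exact two-means and the stepwise search are fully
deterministic; MixedLM optimisation falls back from the default BFGS
through Powell/Nelder–Mead/CG because a boundary random-intercept
variance (σ²_u → 0) can make the BFGS Hessian singular; beta responses
landing on 0/1 in simulation are nudged inside the open interval by
machine epsilon and counted.

## The synthetic deployment generator

The simulator emulates the data-generating process the pipeline
assumes, with every quantity's truth recorded: dives of 700–1800 s to
200–650 m (bounded by transit feasibility at the drawn pitch) separated
by 120–180 s surfacings; smooth vertical-speed profiles (cosine ramps
over an 8-s body-reorientation timescale) integrated to depth, so
`depth-rate = swim_speed · sin(−pitch)` holds exactly; sine-shaped
wiggles (8–16 m, 25–45 s) and trapezoidal steps (0.1–0.3 m/s, 20–40 s)
placed disjointly in the bottom span; heading as a per-second random
walk, more sinuous at the bottom (6°/s vs 1°/s steps); a 5° slow roll
wobble. The swim speed is a configurable constant, 2 m/s by default,
with no claim of realism (velocity sensors on these tags commonly
fail). Strike bursts are 3–8 Hz band-limited noise with a Tukey
envelope at 0.4 g RMS on all three axes (two-axis variants serve as
negative controls), Poisson-placed in bottom phases at 0.8 min⁻¹ at
400 m with a negative depth trend (e^(−0.4·(depth−400)/200)), so the
count models have signal to find. White accelerometer noise (0.03 g),
depth quantization to 0.5 m before a 0.5 m/h pressure drift is added,
GPS fixes at 60 % of surfacings, and every 10th dive a drift dive
(≥ 300 s passive sink at 0.3 m/s, no stroking) complete the picture.
Identical seed and configuration reproduce the streams bit for bit.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: hydrodynamics and buoyancy (stroking is a
fixed-amplitude sinusoid, not effort-modulated), current advection of
the track, depth-sensor gaps, magnetometer calibration error, prey
handling beyond a stereotyped burst, and between-individual behavioural
heterogeneity beyond random intercepts. Truth angles are upsampled from
1 Hz to 16 Hz with linear interpolation plus 1-s Hann smoothing; without
the smoothing, derivative corners at the knots would leak spurious
broadband power into the detection band — a reminder that at exactly
zero sensor noise the scale-free two-means will cluster *any* residual
structure, which is why negative controls are run at the realistic
noise floor.

## Problem sizes

The test suite exercises: detection on ~40-dive deployments with
200+ injected bursts; segmentation oracle equivalence on 100 random
dives; parameter recovery with 200 replicates per family at n = 1000
(20 individuals for the mixed models); selection behaviour over 100
replicates at n = 500 with 6 candidate covariates. The acceptance
script reruns the same analyses at 50 recovery replicates and three
30-dive deployments. Full suite ≈ 1 minute, acceptance script ≈ 10 s on
one CPU.

## Known limitations

Events are resolved on the 1 Hz state timeline; closely spaced strikes
merge. Slow steps near the depth-quantization floor are fragmented.
Bottom delimitation inherits the event detector's conventions — a dive
whose only activity touches the descent or ascent run is delimited by
the isobath fallback. The drift-dive criterion is a plausible
reconstruction, not a validated classifier. Heading accuracy degrades
as pitch approaches ±90° and is undefined there.
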