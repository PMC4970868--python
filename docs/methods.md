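# Methods

This note documents the models implemented in `echoplace`, the defaults and
the reasoning behind the open design choices, and what the synthetic data do
and do not establish.

## Acoustic forward model

A scene is a set of ideal point reflectors.  The echo train recorded at a
device pose for a gaze direction is

* the saturating pickup of the emitted call at t = 0 — a full-scale clipped
  copy of the call (its exact shape is irrelevant because the first 5.8 ms
  of every cochleogram are blanked);
* for each reflector at range r and angular offset θ from boresight, a copy
  of the call delayed by 2r/c and scaled by `strength · gain(θ) / r²`
  (spherical spreading both ways, reflectivity referenced to 1 m);
* white Gaussian device self-noise.

The call is a hyperbolic (linear-period) FM sweep, instantaneous frequency
f(t) = f₀f₁T / (f₁T + (f₀−f₁)t), 100→40 kHz in 1 ms, with 5% cosine edge
tapers to limit spectral splatter.  The beam is a Gaussian taper in dB —
attenuation 3 dB × (θ/θ₃(f))² with the −3 dB half-angle θ₃ scaling inversely
with frequency and equal to 10° at 55 kHz — and is evaluated once per echo
at the 55 kHz reference frequency.  Speed of sound defaults to 343 m/s
(20 °C air) and is configurable.  Atmospheric absorption is omitted by
default.  Echo insertion skips reflectors whose beam gain falls below 1e-4
(≈ −80 dB); the approximation error is far below the device noise.
Microphone offsets form a planar sunflower array ≤ 5 cm across; their delay
differences are retained in synthesis but are second-order for templates,
which average across microphones.

Device self-noise defaults to 1e-3 (linear amplitude, call pickup = 1).
The value is a free parameter of the synthetic device: it is chosen so that
reflector-free recordings produce a small but non-zero template floor, as a
real device's internal noise does.  After the 0.4-power compression this
noise sits near 0.06 template units, about an order of magnitude below a
single-echo template peak at 2 m.

## Auditory periphery

Per channel: gammatone bandpass → half-wave rectification → magnitude^0.4 →
second-order Butterworth low-pass at 1 kHz (12 dB/octave).  The filterbank
has 15 centre frequencies, 30–100 kHz in 5 kHz steps.  The gammatone filters
are 4th-order IIR designs with ERB-style (Glasberg & Moore) bandwidths
extrapolated to ultrasonic centre frequencies; filter order and bandwidth
are exposed through `CochlearParams` because the periphery-model family
leaves them open, and order 4 is the standard choice.  Rectification
precedes compression because a power law on signed samples is undefined.

Dechirping aligns each channel's activation maximum — dominated by the call
pickup — across channels.  The alignment target is the *earliest* channel
argmax, so all shifts are leftward and only zero-padding at the end is ever
needed.  Ties in a channel's maximum resolve to the earliest index
(`argmax` convention); an all-zero channel is left unshifted and logged.
Dechirping replaces the channel-wise call–echo autocorrelation of the
original periphery model family: with a saturated call pickup the clean call
is unavailable, and aligning on the pickup maximum has the same effect of
removing the sweep's cross-channel delay structure.

## Template construction

Order of stages: cochleogram → dechirp → blank → collapse → spatial average
→ downsample → repeat mean.

* **Blanking**: every sample with t < 5.8 ms is zeroed — 1271 samples at
  219 kS/s (5.8 ms × 219 kS/s = 1270.2; the boundary rounds outward to be
  conservative about call contamination).  5.8 ms is ≈ 1 m of two-way range.
* **Collapse**: unweighted mean over the 15 frequency channels and all
  microphones, per (direction, repeat) — 651 raw profiles per position at
  full scale.  Templates deliberately carry no spectral information.
* **Spatial average**: each direction's profile is replaced by the mean over
  its 3×3 grid neighbourhood (azimuth and elevation index ±1), truncated at
  grid edges — the −150..150° azimuth range does not close the circle, so
  there is no wrap.  This widens the narrow emitter beam to a batlike
  virtual beam.
* **Downsampling**: 350 µs bin means (97 bins in 34 ms; the trailing partial
  bin is discarded).  Bin means rather than decimation: the 1 kHz low-pass
  has already limited bandwidth, and bin means are the natural reading of a
  temporal *integration* interval.  1/350 µs = 2.857 kHz; the interval, not
  the rounded rate, is authoritative.
* **Repeat mean** comes after spatial averaging, exactly as the pipeline is
  ordered above.

Elevations run −25° + 10.8°·k, k = 0..6 (top row 39.8°).  Direction indices
are 0-based and elevation-major.

## Noise model and classification

The noise floor n_f is the global maximum template value over a
reflector-free run (device pointed at open sky); stored template values
below n_f are clamped to n_f.  Gaussian noise variance σ_n² is calibrated on
a just-noticeable-difference pair: a single point reflector on boresight at
2 m, synthesized noiselessly and processed by the full pipeline on a 3×3
gaze neighbourhood (so the centre direction receives its complete spatial
average), and a sibling with the echo scaled by 10^(2/20).  For two
templates at Mahalanobis separation d the two-alternative correct rate is
Φ(d/2), so the 75% criterion fixes σ_n = ‖ΔT‖/(2 Φ⁻¹(0.75)); the closed
form is verified by Monte Carlo.  The calibration range and reflectivity
(2 m, strength 1) are configuration parameters; the closed-form property
holds for any choice.  One global σ_n² is shared by all templates.

Flooring is applied to *stored* templates before calibration and
classification; Monte-Carlo draws are not re-floored by default (the floor
models the device, the Gaussian noise models perceptual noise) — a switch on
`NoiseModel` restores re-flooring.  Nearest-template assignment breaks exact
ties uniformly at random (seeded), which is what makes N identical templates
share P_c = 1/N.  The running P_c estimate is checked every 50 draws and
stops when it changes by less than 0.01, bounded to 100–1000 replications.

The expected angular error weights great-circle distances between gaze
directions by the confusion posterior; confusions with other positions'
templates enter through their direction labels only (the error is angular).

## Catchment analysis

Dissimilarity curves start at (0, 0) and are scanned outward.  A decrease
smaller than 1% of M (the median Mahalanobis distance over all template
pairs of the data set) does not break the monotone run; the catchment is the
largest separation inside the run whose dissimilarity has reached at least
10% of M, and 0 if that level is never reached.  The same 1%/10% rules are
applied to both linear and angular catchment for consistency (a `strict`
flag restores strict monotonicity for the angular case).  Angular
separations on the az/el grid are continuous great-circle values binned at
10° (the azimuth step) before averaging.  Linear curves average the two
transect directions at each |Δx| where both exist; endpoint positions have
one-sided curves and enter the per-direction median as-is.  The per-(x, ϕ)
catchment is the monotone run length itself; the per-direction summary is
the median over positions.

Spearman's ρ between P_c and catchment distance carries a Fisher-z 95%
interval; the two-site comparison uses the Wilcoxon rank-sum statistic.
Degenerate inputs (constant P_c) yield a report flagged not-applicable.

## Synthetic experiments

Habitat archetypes for the spot design are homogeneous Poisson clutter in a
12 m × 12 m × 6 m box around the device: densities 0 (open), 0.08
(semi-cluttered) and 0.5 (cluttered) reflectors/m³ with lognormal
reflectivities around 1 — chosen so the open/semi/cluttered contrast spans
chance-level to near-certain classification.  A keep-out radius of 0.5 m
around the device excludes physically impossible reflectors.

The corridor contrast pairs a *boulder corridor* — a continuous rough rock
wall 5.2 m from the transect line, reflector positions Poisson along-track
(≈3/m), strengths lognormal around 5, piled from −0.5 to 2 m height — with a
*vegetation corridor* — dense weak foliage (strengths ≈ 0.2) on walls only
0.9 m away with ~1.5 m of vertical extent.  Both walls have vertical
structure so off-horizon gaze directions still receive echoes; isolated,
strictly periodic boulders were rejected during design because periodicity
produced artificial quasi-periodic dissimilarity curves and echo-free gaze
rows coupled zero catchment with zero P_c, which no natural rock corridor
exhibits.  The physics behind the trade-off is motion parallax: near
reflectors sweep through the 20° beam quickly (fast template change → high
P_c, short catchment), distant strong reflectors change slowly (slow change
→ long catchment, more confusable templates).

Problem sizes: full-scale configurations reproduce the study geometry (31
microphones, 31×7 grid, 12-spot and 50/40-position transects).  The
pre-packaged smoke configurations — chosen as the package's default test and
demonstration scale — use 2 microphones, the full 31×7 grid for spot
experiments (the 1/217 chance level requires the full panorama), an 11×3
grid with 16 positions × 0.25 m for corridor experiments, and 3 repeats
throughout.  A complete corridor runs in ~30 s on one CPU; a spot position
in ~10 s.

## What the synthetic data show — and do not

The generator emulates the sampling design, the call, spherical spreading,
beam directivity and device noise.  It does not model surface scattering,
diffraction, atmospheric absorption, wind, or the frequency dependence of
real reflectors; reflectivities are scalar.  Passing tests therefore
establish that the *pipeline* reproduces the qualitative structure the
analysis predicts — chance-level classification in open scenes, reliable
classification in clutter, and the catchment/classifiability trade-off
between strong-distant and weak-near reflector corridors — not that any
particular field habitat yields particular numbers.  Statistics measured on
the original field recordings (mean catchment distances, site-specific
correlation coefficients and rank-sum statistics) depend on those
recordings and are out of scope; the package reports only quantities it
computes from its own inputs.

## Numerical notes

* All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; per-train seeds derive from (master, position, direction,
  repeat, mic), so datasets are bit-identical for equal seeds regardless of
  iteration order.
* Low-pass filtering can ring marginally below zero; activations are clamped
  at 0 (they are defined non-negative).
* Template CSV files are written with `%.17g` and read with pandas'
  round-trip parser, so they round-trip float64 exactly; HDF5 echo
  containers store float64.
* Exact distance ties in classification are detected with an absolute 1e-12
  slack on squared distances before uniform tie-breaking.
* The calibration reference keeps its echo well below the saturated pickup;
  if an echo rivals the pickup amplitude, the dechirp alignment can switch
  from pickup to echo and break the pair's exact 0.4-power scaling (this is
  physical, not an artefact, and the calibration default of 2 m avoids it).

## Known limitations

* The beam is applied as a scalar gain at the reference frequency; a
  frequency-resolved beam would slightly recolour echoes from off-axis
  reflectors.
* Extended objects are clusters of points; no occlusion or multiple
  scattering.
* The angular-catchment bin width (10°) matches the azimuth step; much finer
  bins on the 31×7 grid leave some bins empty and are skipped.
* `classify_all` is O(n_templates² · draws); transect pools beyond ~10⁴
  templates need batching beyond what the smoke configurations exercise.
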