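# Methods

This note documents the models, estimators and numerical choices behind
`mini2p_tuning`, and what the synthetic-data generator does and does not
emulate.

## Signal conditioning

Raw per-ROI fluorescence is corrected by fixed-coefficient neuropil
subtraction, `F_corr = F_cell − 0.7·F_np`. The slow baseline is
`F0(t) = F_s(t) + m`, where `F_s` is the running 8th percentile of `F_corr`
in a ±15 s window (truncated, not padded, at the session edges) and `m` is a
constant offset. The offset is defined here as the median of `F_corr − F_s`
over *baseline points* — frames whose local standard deviation (±15 s) stays
below `std_min + 0.1·(std_max − std_min)` — so that the residual
`F_corr − F0` is centred at zero during quiescence. An all-constant trace
degenerates to `std_min = std_max`; every frame then counts as a baseline
point and `m = 0`.

ΔF/F is `(F_corr − F0)/F0`; a baseline magnitude below tolerance raises an
error naming the offending frame rather than silently dividing. Significant
transients are maximal runs where ΔF/F exceeds 2× the local baseline noise
(the running std of `F_corr` expressed in ΔF/F units) for strictly more than
0.75 s.

Deconvolution solves a non-negative least-squares problem against a constant
exponential kernel (decay 1.5 s, the GCaMP6s time constant) using a pool
adjacent violators pass over the AR(1) reformulation
(`gamma = exp(−1/(decay·rate))`). On noise-free traces this recovers event
frames and amplitudes exactly (to float tolerance), which the tests exploit.
Deconvolution runs on `F_corr − F0` so the slow component cannot leak into
events. The event series is gated by the transient mask and rescaled so its
maximum equals the maximum of the gated ΔF/F; a *calcium event* is a maximal
run of consecutive nonzero gated samples — the run reading resolves the
ambiguity between per-sample and per-burst counting, and the `>100 events`
eligibility gate is applied to run counts.

SNR is the mean of within-transient 90th percentiles of ΔF/F divided by the
mean absolute successive difference of ΔF/F outside transients. The
"absolute successive difference" reading is chosen because a signed mean of
differences is ~0 by construction; no-transient traces report SNR 0 with a
flag, zero-noise traces +inf with a flag.

## Tracking

Head position is the midpoint of the two ears; coordinates are mathematical
(y up), and image-pixel tables are flipped on ingestion so "anticlockwise"
is unambiguous. Positions are smoothed by centred linear-regression windows
of 0.2 s (3 frames at 15 Hz) applied independently per window; for a
symmetric window the fitted centre value equals the window mean, so the
interior is a moving average and only edge frames need explicit truncated
fits. Speed is the inter-frame step length times the frame rate. Head
direction is 90° anticlockwise from the left-ear→right-ear vector;
coincident ears yield a missing value.

Low-likelihood (< 0.5) coordinates are replaced by the mean of the
neighbouring frames. Runs of consecutive flagged frames are filled
iteratively from the outside in: each pass fills every flagged frame that
has at least one resolved neighbour with the mean of its resolved
neighbours (a single neighbour — at a run edge or session boundary — is
copied).

Tortuosity is path length over chord length in a ±1.25 s sliding window,
computed on positions smoothed with an additional 0.5 s moving average; it
is undefined at session edges and where the chord is below tolerance. The
turning thresholds used by the open-field metrics (tortuosity 1.96, running
speed 7.3 cm/s) were calibrated on unimpeded control animals in the source
data; they are injected parameters here, never recomputed.

## Tuning maps

Maps are occupancy-normalised: per bin, summed event amplitude over seconds
spent, after discarding frames slower than 2.5 cm/s. Defaults: 2.5 cm
spatial bins with 3 cm Gaussian smoothing; 3° directional bins with 6°
circular smoothing; 1.5 cm/s speed bins with 3 cm/s smoothing. Bin grids
are anchored to the arena walls and a partial edge bin is kept. A bin is
visited at ≥ 0.1 s occupancy. Smoothing is applied to the ratio map (the
literal reading of the construction) with missing-aware kernel
renormalisation, so unvisited bins neither receive nor donate mass — the
package asserts mass conservation pre-smoothing as an invariant.

The spatial autocorrelogram is the Pearson correlation of the map with
itself at every 2D lag over mutually valid bins; lags with fewer than 20
common bins are missing (the minimum-overlap guard is this package's
choice). Numerically-zero variance at a lag is clamped to missing rather
than letting FFT round-off produce spurious ±1.

The visual-field-sign map is the sine of the signed angle between the local
azimuth and altitude gradients, missing where either gradient vanishes.

## Classification

Null distributions come from circular time shifts of the whole event
sequence by a uniform draw in [30 s, T − 30 s] (whole frames, wrapped), which
breaks the activity–behaviour coupling while preserving the activity
autocorrelation. Thresholds are the 95th percentile of each cell's own null;
permutation counts follow the regional presets (200 for VC, 1,000 for
MEC/CA1). Because binning indices and occupancy depend only on behaviour,
a full null distribution reduces to batched weighted histograms of the
rolled event series; one RNG stream per cell is derived from
(session seed, cell id).

* **Place**: spatial information `Σ p_i (λ_i/λ) log2(λ_i/λ)` above its
  null, half-session map stability (Pearson over bins visited in both exact
  frame-count halves) above its null, and at least one place field —
  an 8-connected component of bins above 20% of the map peak with area in
  [9, 625] bins and mean rate above 0.1 (VC) or 0.02 (CA1) ΔF/F·s⁻¹.
* **Head direction**: mean vector length of the smoothed directional curve
  above its null, plus half-session directional stability. The preferred
  direction is reported as the circular mean of the curve (less bin noise
  than the argmax).
* **Grid**: grid score above its null plus geometry validity.
* **Conjunctive**: grid and head-direction criteria both passed.
* **Escape-active**: distinction score `(F_esc − F_other)/(F_esc + F_other)`
  from mean ΔF/F inside versus outside the escape frames, against circular
  shifts of the ΔF/F trace.

### Grid score

The central circular sample of the autocorrelogram is correlated with
itself rotated by 60° and 120° (group 1) and by 30°, 90°, 150° (group 2);
an annulus scores `min(group 1) − max(group 2)` — the strictest reading of
"minimum difference between any of the elements" — and the cell's score is
the maximum over annuli. The annulus schedule: inner radius at the first
local minimum of the angularly averaged autocorrelogram (central-peak
exclusion), outer radius swept from inner+2 bins to the largest inscribed
circle in 1-bin steps. Rotation is bilinear resampling on the lag grid
about the centre bin; bins missing in either copy are excluded from the
correlation, and an annulus is discarded if any rotation leaves it with
fewer than 20 valid bins or zero variance.

The max-over-annuli selection gives even unstructured maps a small positive
score offset (simulation in the test suite: mean ≈ 0.15 for white noise).
This is inherent to the estimator's definition and harmless for
classification, because observed scores are always compared with shuffle
nulls computed by the same estimator.

### Grid geometry

Fields are 8-connected components of autocorrelogram bins above a
correlation threshold (default 0.3, adjustable 0–0.5 with scale); the
component containing the centre is the central peak. Spacing is the mean
distance of the six nearest field centres of mass (weighted by correlation
above threshold). Axis angles live on a 180° circle; the six field angles
are clustered with a 15° tolerance and anything other than exactly three
clusters is reported as unresolved geometry (this is how a square lattice,
with four axes, fails). Axis 1 is the axis closest to the horizontal
reference; orientation is the arithmetic circular mean of the three axes
after mapping Axes 2–3 within ±30° of Axis 1; the orientation offset is the
smallest axis angle to the north–south wall (both references are
parameters, since the reference anchoring — 0° versus 90° — is a convention
choice).
Validity requires all interaxis angles in (30°, 90°) and all field-distance
ratios within [0.5, 2].

## ROI bookkeeping

Overlap ratio is `min(shared/|A|, shared/|B|)`. Plane duplicates are pairs
from adjacent planes meeting **any** of: centre distance < 15 µm, overlap
> 0.5, ΔF/F correlation > 0.5. The source text supports both a disjunctive
and a conjunctive reading; the disjunctive one (more removal, fewer
double-counted cells) is the default and a strictness switch exposes the
conjunctive reading. Cross-FOV duplicates use the overlap-only rule at the
deliberately stricter 0.75. Duplicate pairs are merged transitively before
the keep rule — only the member with the highest mean ΔF/F survives, ties
to the lower id. Stitching refinement searches integer offsets within ±5 px
maximising normalised cross-correlation of the overlap; a flat overlap or a
boundary optimum is flagged. The per-frame non-rigid motion summary is the
maximum over block pairs of the root-sum-square block-shift difference.

## Scanner geometry and distortion

The closed forms `x = L/sin(α)·tan(θ2)`, `y = L(cot α − 1/cos²θ2)`,
`cos β = cos α·cos θ2` (α = 45° − θ1; degrees at the interface, radians
internally) are evaluated exactly. The sampled footprint quantifies the
trapezoid shape (waist = minimum fast-axis line width, height = slow-axis
extent; the ratio approaches √2/2 for equal half-angle ranges) and the
curvature of constant-θ1 lines. The working region is the open
amplification band minus the closed ±20% neighbourhood of the first
resonance, matching the strict inequalities of the printed constraints.

Distortion calibration is a Delaunay-triangulated piecewise-affine map
taking measured anchor points exactly onto the ideal lattice; outside the
hull, the nearest triangle (by centroid) extends the map — the interactive
original leaves extension unspecified. Anchor detection replaces manual
dragging: the image is correlated with a plus-shaped kernel, the response
maximum near each expected crossing is refined per axis by parabolic
interpolation, and detections pair to the nearest ideal cross. Images are
corrected by inverse mapping with bilinear interpolation (edge-extended).

## Synthetic data

The generator defines the study conditions for every test:

* **Trajectory**: 80×80 cm arena, 15 Hz, 30-min sessions. Heading is a
  persistent angular random walk, speed an Ornstein–Uhlenbeck process
  (mean 10 cm/s, relative sd 0.35) clipped at zero, walls reflect. The
  source data constrain only summary behaviour (coverage, speeds), not a
  generative model, so this is the simplest process matching those
  summaries. Four body parts are emitted with constant 2 cm ear separation.
* **Rates**: place = Gaussian bump; grid = rectified three-cosine
  interference (wave vectors offset 30° so `orientation_deg` names the
  lattice axis a user measures); head direction = von Mises; conjunctive =
  product; escape = gain on flagged frames.
* **Events**: per-frame Poisson thinning of the rate, log-normal amplitudes
  (unit median, sigma 0.5).
* **Traces**: AR(1) exponential kernel (value = amplitude at the event
  frame), Gaussian noise, and a shared slow neuropil fluctuation mixed in
  by `neuropil_fraction`. The pipeline demo uses amplitude_scale 25 on a
  baseline of 100 fluorescence units so single events land at ΔF/F ≈ 0.25,
  the size of real GCaMP6s transients — without this the 0.1 ΔF/F·s⁻¹
  place-field floor would reject everything.
* **Footprints**: disk ROIs on a well-separated jittered grid with planted
  plane/FOV duplicates at a requested overlap, sharing traces.
* **Calibration targets**: Gaussian-profile grid lines; warps are forward
  displacement fields, inverted per pixel by fixed-point iteration, with a
  Jacobian check rejecting folding warps.

What the generator does **not** emulate: imaging noise structure beyond
white Gaussian + slow neuropil (no motion artefacts, no bleaching),
anatomically realistic ROI shapes, theta-modulated or behaviour-state-
dependent firing, and remapping. Passing tests therefore demonstrate the
correctness and calibration of the estimators under their stated model, not
robustness to every pathology of real recordings.

## Problem sizes

The test suite and the acceptance script run sessions of 27,000 frames
(30 min at 15 Hz), 200–1,000 permutations per cell, populations of up to
400 untuned cells for null calibration, 100-ROI fixtures with 50 planted
duplicates, and 256-px calibration targets. These sizes keep every
calibration quantity (binomial bands around the 5% false-positive rate,
one-bin spacing recovery) statistically meaningful while remaining
desk-scale.

## Known limitations

* The pool-adjacent-violators deconvolution assumes the stated exponential
  kernel; model mismatch (rise times, varying decay) is not handled.
* Grid geometry needs six clean inner fields; weak or edge-truncated
  autocorrelograms return invalid geometry rather than a guess.
* The population-ratio null re-evaluates a caller-supplied criterion; with
  per-cell shuffle thresholds this is the pragmatic reading of an
  under-specified procedure.
* `escape_active` shifts the ΔF/F trace; the alternative reading (shifting
  deconvolved events) is a one-line switch at the call site.
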