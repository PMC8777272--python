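# Methods

This note documents the models behind each module, the defaults and why
they were chosen, and what the synthetic-data generators do and do not
emulate.

## Stimulus synthesis

Gratings are built as truncated odd-harmonic series of a square wave
(amplitudes ∝ 1/k), with three modes:

* **square** — harmonics k = 1, 3, …, 2·n_harmonics − 1;
* **missing fundamental** — the same series with the k = 1 amplitude set
  exactly to zero;
* **third harmonic** — a square wave at three times the fundamental spatial
  frequency (bar width divided by 3), serving as a control whose features
  and Fourier energy agree.

The truncated series is chosen over FFT-notching a two-level square wave
because the harmonic amplitudes are then analytically controlled and the
1/k ratios, the Parseval relation between the two stimuli, and the exact
zero at the fundamental are directly testable.  An ideal two-level square
wave is available via `n_harmonics=None`.

**Luminance convention.**  The square-wave mode is affinely mapped to span
exactly `[lum_min, lum_max]` (defaults 8 and 800 lux, Michelson contrast
0.98).  The missing-fundamental mode reuses the *square wave's* scale
factor: removing a Fourier term changes the extrema, and re-normalizing
would distort the harmonic ratios that define the stimulus.  Mean luminance
is `(lum_min + lum_max)/2` in every mode, so average light flux is
conserved across conditions.  The number of retained harmonics (default 15)
and the normalization are exposed as parameters because the rendered
stimulus of an experiment may differ in both.

**Animation and apparent direction.**  `frame_sequence` advances the
pattern by a fixed fraction of the fundamental wavelength per frame
(`quarter_cycle_sequence` fixes it at 1/4).  `apparent_motion_direction`
reads the phase of the strongest spatial-frequency bin across frames,
wrapping each phase step to (−180°, 180°].  This principal-interval
wrapping is what turns the third harmonic's +270°-of-its-own-period jump
into −90°, reproducing the perceptual reversal; the independent
`cross_correlation_direction` oracle instead reports the literal pattern
shift (argmax of the circular cross-correlation), and the two deliberately
disagree on quarter-cycle missing-fundamental sequences.

**Screen geometry.**  `warp_to_screen` models a cylindrical screen viewed
from its center with a flat virtual image plane at distance
`radius + throw`: flat coordinate x maps to visual angle atan(x/(radius +
throw)).  The experiment this emulates names no geometry, so the model is
the simplest one that makes angular bar width constant on the screen;
`radius=inf` is the identity.  A flat image plane cannot reach ±90°, so the
warp covers the field its inputs span (tests use ±75°).

**Protocols.**  The standard timeline is 240 s of black screen (spontaneous
baseline), then each condition × direction presented `reps_per_direction`
times (default 20) as 8 s static + 12 s moving, in a seeded uniform
shuffle.  A four-direction variant (30 s moving / 30 s black / 30 s static,
10 repetitions) covers orientation experiments.

## OKR analysis

Eye orientation is the angle of each eye's ellipse against a fixed axis;
per-eye means are subtracted (`zero_baseline`) to remove the animal's
heading.  Saccades are maximal runs of |angular velocity| above a threshold
(default 100°/s — far above pursuit velocities of ~10°/s, well below the
fast phase), merged when closer than a 0.2 s refractory interval; direction
is the sign of the net displacement over the run.  This deterministic
detector replaces the interactive tool such experiments typically use; both
parameters are exposed.

Behavior is sorted per consecutive saccade pair, per eye, pooled across
eyes (conjugate OKR assumed): (+1, +1) → pursuit to the left, (−1, −1) →
pursuit to the right, alternating → spontaneous.  Epochs with fewer than
two saccades count as one spontaneous event — the pair rule is silent
there, and an epoch without repeated resets shows no pursuit.  Sign
convention: +angle is clockwise in image coordinates, so +1 saccades rotate
left-to-right.

`summarize_behavior` converts pursuit labels into stimulus-relative
categories (with/against/spontaneous) using each epoch's direction, forms
per-larva percentages, and runs a one-way ANOVA across the three categories
followed, when p < 0.05, by pairwise Welch comparisons with 95 % CIs.  For
black screens (no stimulus direction) leftward pursuit fills the
"stimulus direction" slot by convention so the three-way split stays
comparable.

## Imaging preprocessing

* **Artifacts:** Pearson correlation of each frame with its predecessor,
  z-scored over the whole recording; frames with z < −3 are flagged.  The
  z population is the full recording (the alternative — a running window —
  is indistinguishable on recordings without slow correlation trends).
  Constant-frame pairs get correlation 1.
* **Registration:** translational only; per-frame integer shift maximizing
  FFT cross-correlation with a template, applied with median edge fill.
  Slow XY drift is translational to good approximation, and integer shifts
  are exactly invertible and testable.  Shifts beyond `max_shift` (default
  20 px) are reported for exclusion instead of applied.
* **Segmentation:** Gaussian smoothing, local maxima (≥ `min_distance`
  apart, above a global percentile floor, default 75th) as markers,
  marker-based watershed on the inverted image restricted to the
  supra-floor mask, area filtering.  The manual curation step of an
  interactive workflow becomes optional editing of the ROI list.
* **Traces:** per-ROI pixel means per frame; artifact frames become NaN and
  are *never* interpolated — they are excluded from every downstream
  window and mean.
* **Cross-animal mapping:** least-squares affine on ≥ 3 non-collinear
  landmark pairs; hemisphere and rostro-caudal labels come from signed
  distances to configured lines (ties go to the positive side: right /
  caudal).  Coordinates are 0-based (row, col); microns only via
  `pixel_size`.

## Calcium events

The baseline is the 8th percentile in a 30 s centered running window,
truncated (not padded) at the trace edges, with NaN frames excluded from
each window's sample; ΔF/F = (F − baseline)/baseline.  Division is the
standard convention; `normalize=False` gives the plain difference.  A
sanity filter drops ROIs whose baseline jumps more than 2× between
consecutive 30 s blocks (dying neurons, focus drift) or whose raw mean is
below a floor.

**Noise model.**  Transients of a nuclear indicator are positive-going, so
the sub-median samples mirrored about the median estimate the symmetric
noise distribution uncontaminated by events: sigma is 1.4826 × MAD of that
mirrored sample.  The median, not zero, is the model's center: a
low-percentile baseline leaves ΔF/F resting ~1.4 sigma above zero, and
testing deviations from zero would label every frame.  A Student-t option
is deliberately not provided; the robust scale estimate already tolerates
heavy tails in the positive direction, which is where all the signal mass
is.

**Detection.**  For each frame, a causal window of ≈ 2 decay constants is
compared under H0 (i.i.d. Gaussian noise around the center) and H1 (an
instant-rise, exp(−t/2.88 s)-decay transient starting at that frame, with
least-squares amplitude floored at 2 sigma).  With equal priors the frame
is significant when log odds ≥ log(confidence/(1 − confidence)), default
confidence 0.95.  The 2-sigma amplitude floor prevents degenerate H1 fits
to noise; the decay anchor is what rejects single-frame spikes whose
following samples revert immediately.  Windows containing artifact frames
drop those samples from both hypotheses and require at least a quarter of
the window to be valid.  On pure-noise simulations the empirical
false-positive rate is far below the nominal 5 % (the decay constraint is
conservative); detection power is monotone in transient amplitude.

## Response census

Frame spans come from `floor(onset × rate)` half-open arithmetic (8 s at
3.91 Hz → 31 frames).  The activity measure is the significant-frame
indicator by default (ΔF/F works too); per condition,
delta = mean(activity during the condition's moving spans) − mean(activity
during the leading black epoch), and z standardizes delta across the ROI
population.  ROIs with z < −1 are ineligible for that condition *before*
the responsiveness test, which requires ≥ 4 significant frames (≈ 1 s)
within a repetition's span in ≥ ceil(half the repetitions), counted per
direction.  The black mean uses only the leading black epoch, not
inter-trial screen states.

Profiles over the six moving conditions give 2⁶ = 64 possible patterns
(2⁴ = 16 for the orthogonal variant); the all-zero pattern is a
non-responder and stays in percentage denominators but is not a census
row.  The census keeps patterns reaching ≥ 0.1 % of a region's pooled
recorded neurons in either region, compares regions per pattern with the
two-sided Wilcoxon rank-sum test across larvae (exact null for tie-free
groups of ≤ 10, normal approximation with tie correction otherwise), and
adjusts across retained patterns with Benjamini–Hochberg.  Percentages are
computed per larva (the z-score population is also per larva, not pooled);
both the pooled-region percentage and the per-larva median are reported
because "fraction of all recorded neurons" and "fraction of responding
neurons" answer different questions.

## Synthetic data

The generators emulate the study conditions rather than any particular
recording: 3.91 Hz sampling, 256×256 frames, 2.88 s indicator decay,
8 s/12 s static/moving epochs after a 240 s black baseline, 20 repetitions
per direction at full scale (5 in the reduced session used by the heavier
tests, with 200 neurons and SNR 5 — sizes chosen so the full suite runs in
well under a minute of simulation time).

* **Traces:** Bernoulli-per-frame events (simplest process with exact
  ground truth) at 5·10⁻⁴/frame spontaneous (~0.12 events/min — the sparse
  end of spontaneous activity as seen through a slow nuclear indicator,
  which only reports strong bursts) and 0.35/frame inside the spans of a
  neuron's planted pattern; events convolve with the instant-rise
  exponential kernel, scale to snr × noise sigma (defaults 5 × 0.05), and
  ride on a ±5 % slow multiplicative baseline drift plus Gaussian noise.
* **Movies:** Gaussian nuclei (sigma = radius/2) modulated by their traces
  over a constant background, sqrt-intensity shot-like noise, optional
  linear drift, and whole-frame random translations at `artifact_rate` as
  movement artifacts.  `min_spacing` gives non-overlapping placements for
  segmentation benchmarks; `caudal_bias` plants spatial lateralization.
* **Eye traces:** during moving epochs, a stationary sawtooth — pursuit at
  6°/s toward the stimulus' Fourier-energy direction (opposite to the
  pattern shift for the missing-fundamental and 3rd-harmonic conditions;
  the mapping is a parameter, so both hypotheses are testable), reset every
  2 s; during black/static epochs, alternating ±8° saccades every 4 s;
  conjugate eyes with independent 0.2° Gaussian noise.

What the generators do **not** emulate: biophysical calcium dynamics
(nonlinear indicator response, rise-time kinetics), optics beyond Gaussian
nuclei, neuropil or bleaching, vergence or non-conjugate eye movements, and
any correlation structure between neurons.  Passing recovery tests
therefore show that the pipeline's inference is correct *for its own model
class* at realistic noise levels — they do not certify performance on real
recordings with model mismatch.

## Numerical choices and edge cases

* Percentiles use linear interpolation everywhere (baseline oracle tests
  are exact, not approximate).
* The epoch-index frame arithmetic is floor-based and half-open; spans tile
  a recording without overlap.
* Degenerate inputs raise: non-uniform eye-trace sampling, collinear
  landmarks, empty ROIs, zero-variance ΔF/F (unless a sigma floor is
  passed), zero population spread in the z-score.
* Flat luminance series have no dominant Fourier component and raise
  rather than returning an arbitrary direction.
* All generators are deterministic given their seed; derived seeds stay
  within 32-bit range.

## Known limitations

* The odds-ratio detector models one transient per window; overlapping
  transients are detected but their amplitudes conflate.
* Translational registration cannot correct rotation or non-rigid
  deformation.
* The behavior summary assumes conjugate eyes; truly monocular paradigms
  need per-eye summaries (the saccade detector already reports the eye).
* With very few repetitions the "half of the repetitions" rule becomes
  lenient (1 of 2); reduced-scale analyses should keep ≥ 5 repetitions.
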