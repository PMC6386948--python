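# Methods

## Signal model and scope

The package analyses single-channel vibration traces from a sheet-type
piezoelectric (PVDF) sensor with a seated or lying person on it. The
cardiac component of such a trace is modelled as a phase-locked harmonic
comb: every heartbeat advances a common cardiac phase φ(t) by one cycle,
and the k-th harmonic contributes a_k·cos(2π k φ(t) + φ_k). Respiratory
sinus arrhythmia makes the beat-to-beat interval fluctuate; we bound that
fluctuation by a hard envelope of ±100 ms around the nominal period (≈1 s),
drawing each interval independently and uniformly inside the envelope — a
uniform draw respects a stated hard bound exactly, which a Gaussian would
not. In a subset of people the ~1 Hz fundamental is nearly absent and the
energy appears as higher harmonics amplitude-modulated at the heart rate;
the model reproduces this by applying an AM factor (1 + m·cos 2πφ) to
harmonics of order ≥ 2.

Respiration itself (< 0.6 Hz), autonomic heart-rate-variability spectral
analysis (0.0033–0.4 Hz), and any hardware concerns are out of scope: the
pipeline removes everything outside 0.6–15 Hz and works purely on the
spectral shape inside that band.

## Preprocessing

**Stable-segment selection.** The analysis unit is one 10-s stretch free of
body-movement transients. Selection is automatic: a 10-s window slides in
1-s steps; within each window the RMS of its ten non-overlapping 1-s
subwindows is computed (after removing the recording mean) and the window's
*stability score* is max/median of those RMS values. A stationary biosignal
scores ≈ 1; an amplitude transient inflates the maximum. The minimum-score
window wins, with exact ties (beyond a 1e-10 float guard) going to the
earliest start. The score threshold for flagging a recording as having no
clean stretch defaults to 3.0. This numeric criterion is our own stand-in
for what a human operator would do by eye; it is scale-invariant, so sensor
gain does not affect the choice.

**Band-limiting.** A zero-phase frequency-domain mask: remove the mean,
multiply the rfft by a raised-cosine band mask, invert. This avoids filter
order/phase choices entirely and is exactly linear. The 0.1 Hz-wide
raised-cosine transitions sit *just inside* the band edges (mask 0 at
0.6 Hz and 15 Hz, 1 from 0.7 and up to 14.9 Hz): everything outside the
band is removed entirely rather than attenuated, at the cost of a soft
shoulder on the innermost 0.1 Hz of the passband, where essentially no
cardiac harmonic lives. A mask centred on the edges would instead leave a
measurable (≈1%) out-of-band remnant for broadband input, violating the
band-compliance contract the tests assert. A second application of the
filter only affects shoulder content; for cardiac-band signals the change
is below 1% RMS (for white noise, whose shoulder content is maximal, it is
necessarily larger — the idempotence guarantee is stated for band-typical
signals).

## Spectrum

One Hann-windowed periodogram of the full 10-s segment (density scaling),
bins outside 0.6–15 Hz discarded: Δf = 1/duration = 0.1 Hz, 145 bins.
Welch averaging is deliberately not used — splitting 10 s would destroy the
0.1 Hz resolution that separates adjacent heartbeat harmonics. The window
function is not dictated by the problem; Hann is the default and is exposed
nowhere else, keeping the estimator deterministic.

Before feature extraction the spectrum is smoothed with a 3-bin
*conservative spreading* average: each bin's power is distributed equally
over its centred window clipped at the band edges. For interior bins this
equals the ordinary moving average; unlike the plain shrinking-window mean
it conserves Σ power·Δf exactly, so smoothing and normalization commute.
Width 1 disables smoothing.

Normalization divides by the rectangle-rule integral Σ power·Δf over the
retained band, making the integral exactly 1. The band integral (rather
than an all-frequency integral) is used because out-of-band content was
deliberately cut. Rectangle rule rather than trapezoid: the difference is
O(Δf) and immaterial at 0.1 Hz, but one convention must be fixed for
bit-stable results. Normalization makes every downstream feature invariant
to sensor gain.

## Features

Let P* be the global maximum of the normalized, smoothed spectrum, and
θ_f = f·P* for the two power standards f = 1/2 and 1/4.

- A bin k is a **peak** at standard f iff P[k] > θ_f, P[k] > P[k−1] and
  P[k] ≥ P[k+1]; plateaus are credited once, to their leftmost bin; at the
  band edges the one-sided test applies, so the global maximum is always
  countable. "More than" the threshold is read as strict inequality.
- A peak's **region** is the maximal interval around it on which the
  linearly interpolated spectrum stays ≥ θ_f, bounded by the interpolated
  threshold crossings or the band edge. Linear interpolation of the sub-bin
  crossing stabilizes areas against bin phase at the coarse 0.1 Hz grid.
- Its **excess area** is the trapezoid integral of (P − θ_f) over the
  region — the convex-upward cap the standard cuts off. The cap (not the
  total area under the curve) is used so that sharpness does not depend on
  baseline power far from the peaks.
- Peaks whose regions coincide (several maxima inside one above-threshold
  excursion) each count toward the peak number, but the shared region's
  area is counted once.

The peak-shape number is N = (N₁/₂ + N₁/₄)/2 and the sharpness
S = N/(A₁/₂ + A₁/₄) with A_f the merged total excess area at standard f.
N₁/₄ ≥ N₁/₂ always (a lower threshold admits a superset of maxima), and for
fixed counts S strictly decreases in total area — the sharper the peaks,
the larger S. Whether the areas should be measured on the raw or the
normalized spectrum is not determined by the definitions; we use the
normalized spectrum, which makes both features scale-free.

## Enrollment and identification

Each enrolled session contributes one (N, S) pair. Because S divides area
by peak count, N and S are strongly correlated across any population by
construction; the person-specific content lies in the *deviation* from
that trend. The database therefore fits one ordinary-least-squares line of
S on N over all enrolled sessions (refit after every enrollment) and maps
each measurement to (N, r) with r = S − (β₀ + β₁N). Both dimensions are
z-scored by their population mean and standard deviation (a zero-spread
dimension is dropped from the metric), and a query is assigned to the
subject with the nearest centroid in that plane, ties broken lexically.
The regression needs ≥ 2 distinct N values; `residual()` raises below that,
while identification on a degenerate database falls back to deviation from
the mean sharpness so that a one-subject database still answers.

Evaluation is leave-one-session-out: each session is removed, the line and
scaler are refitted from scratch without it, and the held-out features are
identified against the rest. The report carries top-1 accuracy, confusion
counts, and the median intra- vs inter-subject centroid distance.

## Synthetic subjects and cohorts

No recordings are distributed with the package; the simulator is the data
source for every test. Design choices, in the order the generator applies
them:

- **Target signature.** A subject's identity is encoded as a bimodal
  profile of relative spectral peak heights: one anchor line (the maximum),
  `n_dom` further *dominant* lines at a subject-level plateau r₀ ∈
  [0.66, 0.96] of the maximum power (these exceed the 1/2 standard), at
  most one *mid* line at 0.34–0.40 (counts only at the 1/4 standard), and
  a low floor elsewhere. The target peak number 1 + n_dom + n_mid/2 is
  drawn on a half-integer grid from 1 to 7. The narrow (1/4, 1/2) ratio
  window is used for at most one line because heights there cannot be made
  day-stable.
- **Line placement.** Structured lines occupy the lowest available
  harmonic orders. The features are blind to peak placement, and low-order
  lines have far more reproducible heights: beat jitter broadens harmonic
  h in proportion to z = (h−1)·f₀·jitter, and beyond z ≈ 0.3–0.45 the
  phase noise fragments a line into several ragged maxima.
- **Heart-rate variability.** f₀ ~ U[0.9, 1.3] Hz. The jitter envelope is
  subject-specific (people differ in respiratory sinus arrhythmia), drawn
  up to an order-dependent ceiling that keeps the top structured line's z
  below 0.10–0.25; subjects needing many distinct lines therefore draw
  calmer heartbeats. The hard physiological bound of ±100 ms is never
  exceeded (it is the dataclass default and upper limit).
- **Height realization.** Jitter broadening lowers spectral peaks; the
  attenuation was calibrated against this package's own pipeline over a
  grid of f₀, jitter and order (height ratio ≈ exp(−0.362 z − 1.366 z²)),
  and amplitudes are pre-compensated by the inverse square root so realized
  peak-height profiles track their targets. AM sidebands (at ±f₀ around
  each modulated harmonic) interfere coherently with neighbouring lines;
  amplitudes are solved by fixed-point iteration against the effective
  (sideband-included) magnitudes.
- **Profile kinds.** "fundamental-rich" subjects anchor at order 1 with a
  weak AM (m ≤ 0.25); "am-suppressed" subjects anchor at order ≥ 3 with
  m ∈ [0.5, 0.7] and ≤ 5% of the dominant amplitude at the fundamental, so
  their spectra carry <5% of band power near f₀. The anchor sits at order
  ≥ 3 so its lower sideband stays away from the fundamental position.
- **Nuisance components.** Respiration (0.15–0.35 Hz sinusoid, 1–3× the
  peak harmonic amplitude), white sensor noise at 2–10% of the cardiac RMS,
  and Poisson-count 2-s movement bursts at 5× the cardiac RMS (expected
  once per recording). All three must be removed by the preprocessing
  stage, which the end-to-end tests exercise.
- **Sessions.** A repeat session multiplies each harmonic amplitude by an
  independent log-normal factor with relative spread 1% (default). This is
  deliberately small: the regime being emulated is one in which a person's
  spectral shape is clearly stable across months, and the feature geometry
  amplifies amplitude drift — a line's above-threshold cap scales like
  (r − θ), so a few percent of ratio drift already moves cap areas by
  ~2–3× that. The cross-validated accuracy degrades monotonically as this
  parameter grows, which the acceptance suite checks up to 0.4.
- **Cohorts.** `synth_cohort` assigns enrolled subjects *distinct, evenly
  spaced* target peak-number cells (shuffled), realizing the study premise
  that different people show visibly different spectra; with more than 13
  subjects the cells wrap. About 35% of subjects are drawn am-suppressed.
  Everything is deterministic per cohort seed via spawned seed sequences.

**What the simulator does not emulate.** Real BCG waveform morphology
(I-J-K complexes), posture and chair-coupling effects, heart-rate drift
within a recording, correlated (non-white) sensor noise, and any age
dependence. Passing tests therefore show that the pipeline recovers the
spectral-shape structure this model generates under realistic nuisance
components — not that human cohorts of this size are identifiable at the
same accuracy; the true between-person spread of these features is unknown.

## Numerical choices and degenerate inputs

- Tie-breaks: earliest window in segment selection; lexical subject order
  in ranking; leftmost bin for spectral plateaus.
- All-zero segments propagate a warning and fail at normalization with
  "no signal power in band".
- Spectra with < 3 bins or zero maximum are rejected before peak analysis;
  a zero total excess area (impossible for a bin-sampled spectrum with a
  strict maximum) is guarded anyway.
- Feature CSV values are written with 17 significant digits so read-back
  is exact beyond 12 digits; profile databases are JSON with the fitted
  line and scaler stored alongside the sessions.
- Sampling rates below 30 Hz are rejected (the 15 Hz band edge would not
  be resolvable); two-column time stamps must be uniform within 1% of the
  median step.

## Problem sizes

Default test and evaluation sizes: 3-min recordings at 100 Hz; cohorts of
8 subjects × 3 sessions for identification and 5 cohort seeds × 4
variability levels for the degradation sweep; 200 random spectra against
the brute-force feature oracle and 1000 for count monotonicity. On one CPU
the full test suite runs in well under a minute.

## Known limitations

- With only two dimensions, both bounded, the identification capacity is
  small; beyond ~10 enrolled subjects collisions in (N, r) are expected.
  This mirrors the method's own positioning as a low-capacity
  identification scale.
- Peak counting is threshold-based; a line whose realized height sits near
  a standard can flip a count by ±1/2 between sessions. The simulator's
  level margins make this rare but it is the dominant residual error mode.
- The stability score only detects amplitude transients; a movement
  artifact with the same RMS as the biosignal would pass unnoticed.
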