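# Methods

## Scope and model of execution

stimkit executes declarative psychophysical tests entirely offline. "Real
time" is simulated: the runner synthesizes every display frame and audio
buffer, measures the wall-clock synthesis time of each frame for the timing
report, but never sleeps and never touches a display or sound device. This
makes desk-scale runs deterministic — a test file plus a seed fully
determines the results CSV and settings TXT byte for byte — while keeping
the same dropped-frame accounting a real presentation loop would apply: a
frame is *dropped* iff its compute time strictly exceeds the budget
1000/refresh ms (a frame exactly at budget is not dropped). The measured
percentages themselves are of course properties of the host machine, not of
any display hardware.

## Geometry and units

Degrees of visual angle are converted with the exact chord formula
`size_px = 2 · d · tan(θ/2) · pixels_per_cm`, where `d` is the viewing
distance in cm. The chord form is correct at large eccentricities and agrees
with the small-angle approximation to within ~2 parts in 10⁴ below 5°.
Lengths also accept px, cm and inches (2.54 cm). Durations accept seconds or
frames; seconds are converted by rounding to the nearest frame, ties away
from zero, which minimizes the absolute duration error and maps exact frame
multiples back to themselves. Luminance is carried everywhere as a linear
fraction of the panel maximum in [0, 1]; conversion to cd/m² is a lookup in
the display profile. A small editable device table ships with nominal panel
specs for a few example devices; users are expected to add their own
(nominal maximum-luminance figures vary across panel batches and age, so the
table is a convenience, not a calibration). Gamma/EOTF modelling is out of
scope.

## Visual synthesis

Coordinates: patch-local origin at the stimulus center, +x right, +y up,
angles in radians counterclockwise from +x; stimulus positions are center
coordinates relative to the screen center. All templates are evaluated
analytically at pixel centers (no supersampling).

- **Grating/Gabor**: `L = L̄(1 + c_eff·cos(2π·f·(x cosθ + y sinθ) + φ))`
  with `c_eff = c · G_env · G_mod`; `G_env` is a unit-peak isotropic
  Gaussian (Gabor envelope), `G_mod` a unit-peak Gaussian carrier-contrast
  modulation. `c` is Michelson contrast of the un-enveloped carrier.
  Spatial frequency is written in cycles/degree in test files and converted
  to cycles/px via the chord length of 1°.
- **Checkerboards**: rect parity `(⌊x/w⌋+⌊y/h⌋) mod 2`; radial parity
  `(sector(atan2) + ⌊r/ring⌋) mod 2`.
- **Random dots**: membership coherence — each dot is signal or noise for
  its lifetime; signal dots translate (linear), rotate about the aperture
  center at constant radius (radial), or move along their outward ray
  (expansive); noise dots translate in a per-lifetime uniform random
  direction. Dots that die or exit the circular aperture are redrawn
  uniformly with age 0 and membership re-sampled Bernoulli(coherence), so
  the expected signal fraction equals the coherence.
- **Shapes**: rectangle, ellipse, cross (union of two bars of thickness
  0.2·min(w, h) by default) applied as a binary alpha mask.
- **Noise filter**: additive zero-mean uniform luminance noise of the given
  half-range, identical across RGB per pixel, clipped to [0, 1]. The
  property name is generic and other spectra could be slotted in; additive
  uniform noise was chosen as the simplest well-defined semantics.
- **Noise-bit dithering**: a value v in [0, 1] is stochastically rounded to
  one of its two adjacent 8-bit levels, taking the upper with probability
  equal to v's fractional position, independently per pixel per frame; the
  expected output level equals v exactly, making contrast quasi-continuous
  on an 8-bit panel. Bit depth defaults to 8.
- **Text** is rasterized with a bundled 5×7 monospace bitmap font (no
  system-font dependency); glyph aesthetics are explicitly not part of the
  engine's contract.
- Compositing is back-to-front alpha-over onto a mid-gray (0.5) background,
  with edge clipping; buffers are float32 in [0, 1].

Scenes whose stimuli are provably frame-invariant (no timelines, no dots,
no noise) are rendered once and the buffer reused — including across trials
with identical bound values — which changes no pixel of any frame but keeps
a 140-trial run on a tablet-sized buffer around two seconds. Previews replay
dynamic scenes from frame 0 with the same per-scene RNG stream, so a
previewed frame is bit-identical to the frame a full run produces.

## Audio

Tones are pure sines, `a·sin(2πfi/r)`, with a linear on/off ramp
(default 5 ms, 0 allowed) to avoid onset clicks; frequencies at or above
Nyquist are rejected. Auditory noise is uniform white noise in [−a, a].
Buffers are mono (stereo is out of scope) at the test's audio rate, default
44.1 kHz, with `round(duration·rate)` samples — so 1000 requested 100 ms
tones all contain exactly 4410 samples (zero duration spread at the buffer
level). Scene audio is the sample-accurate sum of event buffers at
`round((onset + av_offset/1000)·rate)`, hard-clipped to [−1, 1] with a
warning; the signed AV offset models a per-device audiovisual asynchrony
correction. WAV output is RIFF PCM16 mono.

## Procedures

- **Constant stimuli**: `all_values_random_order` with R repetitions is R
  independent permutation blocks of the full list (n·R trials, every value
  exactly R times); `fixed` repeats the list's first value; a
  `random_with_replacement` trial draws uniformly.
- **Staircases**: transformed n-up/m-down with fixed additive steps and
  [min, max] clamping. A direction change records the turning-point value as
  a reversal; the staircase stops at a configured reversal count, and the
  threshold estimate is the mean of the last k reversals. The 1-up/2-down
  rule converges on the 2^(−1/2) ≈ 70.7 %-correct level, 1-up/1-down on 50 %,
  1-up/3-down on 79.4 %. Bayesian adaptive procedures (QUEST/Psi) are
  deliberate extension points, not implemented.
- **Observer**: `P(correct) = γ + (1−γ−λ)·F(|x|; α, β)` with logistic or
  cumulative-Gaussian F, F(α) = 0.5. Values enter by magnitude, matching a
  symmetric discrimination task; the side emitted is the correct side with
  probability P.
- **Fit**: binomial maximum likelihood over (α, log β) with fixed γ and λ,
  Nelder-Mead from a deterministic start (median level, slope 4/range), so
  refits are identical. Single-outcome data trigger a boundary warning and
  report the midpoint of the tested range.

## Runner semantics

Sections chain linearly via `next_section` (default: file order; END
terminates). The responder — simulated observer or scripted replay — is
polled once per frame; the first mapped response wins and ends the scene at
that frame, so response time has one-frame resolution (touchscreen hardware
sampling at 120/240 Hz is out of scope). For `left_or_right` responses a
simulated tap left of the screen midline maps to the "left" value. The
trial-wise `correct` column uses the sign convention "positive variable
value ↔ response +1 (right)"; a zero value counts right as correct, which is
immaterial for fitting since P(correct|0) equals the guess rate. At most one
adaptive binding per section is supported, with a 1000-trial safety cap.

## The tutorial fixture and what passing it shows

The packaged tutorial implements an orientation-discrimination experiment:
0.5 s fixation cross, then a 300×300 px elliptical grating (2 cyc/deg,
contrast 0.8) rotated by one of 7 values evenly spaced in [−0.03, 0.03] rad,
all values in random order, 20 repetitions, left/right response, on an
iPad-like 2048×1536 @ 60 Hz profile at 40 cm viewing distance. The default
simulated observer (logistic, α = 0.015 rad, β = 150 rad⁻¹, γ = 0.5,
λ = 0.02, 200 ms response latency) is a plausible mid-experiment human, and
the end-to-end check — run the test, fit the CSV, recover α — exercises
every module at once. What it does *not* show: the simulated observer is
stationary (no learning, fatigue or serial dependence), responds at a fixed
latency, and never times out; real-data effects of that kind are outside
what these tests can certify.

## Numerical choices and degenerate inputs

Frame budgets are reported rounded to 2 decimals (16.67 ms at 60 Hz, 8.33 ms
at 120 Hz). A 1-frame scene evaluates linear timelines at their start value.
Dots at the exact aperture center have undefined ray/tangent; they stay in
place for that update (a probability-zero event for continuous draws).
Michelson contrast of synthesized gratings matches the parameter to 1e−6
when a full period is sampled; mean luminance matches L̄ to ~1e−3 under
integer-pixel sampling. The grating evaluator is cross-checked against a
naïve double-loop reference to 1e−12.

## Known limitations

No GPU rendering, display gamma management, video decoding, real touch
input, vsync or hardware latency measurement; dropped-frame statistics
reflect the host CPU, not a device panel. Import compatibility with test
files produced by GUI experiment builders is not claimed — the JSON schema
here (versioned `"1"`) is its own dialect, designed to be hand-editable.
Conditional section branching (e.g. on accuracy) is not supported; section
order is linear.
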