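# stimkit

A headless, scriptable engine for visual and auditory psychophysics.
Experiments are written as declarative JSON test files — a **test** is a
collection of **sections** (trials), each section a sequence of **scenes**
(e.g. fixation → target → feedback), each scene presenting one or more
**stimuli** — and executed entirely in software: stimuli are synthesized
procedurally frame by frame (visual) and sample by sample at 44.1 kHz
(audio), trials are sequenced by the method of constant stimuli or adaptive
staircases, and simulated observers stand in for a touchscreen. It is aimed
at researchers who want to prototype, pilot, regression-test or power-analyse
psychophysical tests from scripts and CI rather than on a device.

## What it computes

**Stimulus synthesis.** All standard templates are generated analytically at
pixel centers: uniform patches, gradients, gratings/Gabors

&nbsp;&nbsp;&nbsp;&nbsp;*L(x, y) = L̄ · (1 + c·G(x, y)·cos(2π·f·(x cos θ + y sin θ) + φ))*

with Michelson contrast *c*, spatial frequency *f* in cycles/deg (converted
through the display profile), optional Gaussian envelope *G* (Gabor) and
carrier-contrast modulation; rectangular and radial checkerboards;
random-dot kinematograms with linear, rotational and expansive signal motion
and Newsome-style coherence; text; images. Sizes may be given in px, cm,
inches or degrees of visual angle, converted with the exact chord formula
2·d·tan(θ/2)·(px/cm). Contrast finer than the 8-bit panel resolution is
realized by noise-bit dithering: per-pixel per-frame stochastic rounding
between adjacent levels, unbiased in expectation.

**Procedures.** Constant stimuli (fixed / all values in random order per
repetition block / random with replacement) and transformed n-up/m-down
staircases; the 1-up/2-down rule converges on the 70.7 %-correct level.
A simulated observer answers through a psychometric function
*P(correct) = γ + (1 − γ − λ)·F(|x|; α, β)*, and a maximum-likelihood
binomial fit recovers (α, β) from the emitted trial table.

**Timing model.** Each frame has a compute budget of 1000/refresh ms
(16.67 ms at 60 Hz, 8.33 ms at 120 Hz); a frame whose measured synthesis
time strictly exceeds the budget is reported as dropped, with its duration.
Audio onsets can be shifted by a signed per-device AV-offset correction.

## Worked example

The packaged tutorial test measures orientation discrimination: a 0.5 s
fixation cross, then an elliptical grating rotated by one of 7 values from
−0.03 to 0.03 rad (all values in random order, 20 repetitions), with a
left/right response.

```python
import stimkit as sk
from stimkit.runner import ObserverResponder, run_test, write_results

test = sk.load_tutorial_test()
observer = sk.PsychometricObserver(threshold=0.015, slope=150.0)
bundle, timing = run_test(test, ObserverResponder(observer), seed=1)
write_results(bundle, "out")

print(bundle.trials_table.head(3).to_string())
fit = sk.fit_psychometric(list(zip(
    bundle.trials_table["scene2_object1_gratingRotation"],
    bundle.trials_table["correct"].astype(bool))))
print(f"recovered threshold: {fit.threshold:.4f} rad (true 0.0150)")
```

prints

```
   trial   section  scene2_object1_gratingRotation  response  response_time_s  correct
0      0  section1                           -0.01        -1              0.2        1
1      1  section1                           -0.02        -1              0.2        1
2      2  section1                           -0.03        -1              0.2        1
recovered threshold: 0.0130 rad (true 0.0150)
```

Each of the 140 rows is one trial: the rotation presented, the mapped
response (−1 left, +1 right), the response time at one-frame resolution and
whether the response was correct. The fitted threshold (0.0130 rad) recovers
the simulated observer's true 0.0150 rad from 140 trials. `write_results`
emits `settings.txt` (audio rate, screen resolution, frame rate, ...) and
`results.csv` alongside a `timing.json` dropped-frame report.

The same flows are available from a shell:

```
stimkit validate tutorial.stimulitest
stimkit preview  tutorial.stimulitest --scene scene2 --frame 0 --out frames/
stimkit render   tutorial.stimulitest --scene scene2 --out frames/
stimkit run      tutorial.stimulitest --seed 1 --out results/
```

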