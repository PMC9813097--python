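# okrent — optokinetic-reflex entrainment analysis

Tools for quantifying homeostatic plasticity of the optokinetic reflex
(OKR) in larval *Xenopus* semi-intact preparations — and for anyone who
needs a tested, fully synthetic-data-backed pipeline from eye-tracking
video to a plasticity setpoint estimate.

During 30 minutes of oscillating large-field visual motion ("optokinetic
training"), the peak-to-peak amplitude of the tracking eye movements
changes in a way that depends on where it started: animals with large
initial responses down-regulate, animals with small ones up-regulate.
Writing `I` for the immediate response (mean peak-to-peak amplitude over
the first five stimulus cycles) and `E` for the entrained response (last
five cycles), the cohort-level relation is linear,

    ΔA = E − I = m·(I − x₀)

with slope `m` measuring how strongly plasticity depends on the initial
amplitude and `x₀ = −intercept/slope` (the x-axis zero-intercept of the
fitted regression) estimating the homeostatic *setpoint* — the response
amplitude at which training changes nothing.  Intact older larvae show
`m ≈ −0.59`, `x₀ ≈ 6.4°`; younger larvae and animals with transected
climbing-fiber input lose the up-regulation (`m ≈ −0.48` and `−0.29`,
setpoints near zero).

The package covers the whole chain:

- **`synthetic_data`** — triangular stimulus waveforms (4 or 8 °/s; 10 or
  20 s cycles), cohorts of simulated eye-angle recordings obeying a
  parameterized per-cycle homeostatic rule, rendered grayscale eye-phantom
  stacks, ellipsoid phantoms for morphometry.
- **`eye_tracking`** — Otsu segmentation and moment-based ellipse fits;
  eye position = angle of the long axis vs the image horizontal, unwrapped
  frame to frame.
- **`signal_preprocess`** — 200 Hz resampling, zero-phase 4 Hz Butterworth
  filtering, cycle segmentation at analytic stimulus extrema, conjugate
  (left/right) averaging, velocity-based fast-phase exclusion, per-cycle
  peak-to-peak amplitudes.
- **`plasticity_stats`** — immediate/entrained summaries, the ΔA-vs-I
  regression with confidence band and setpoint, SD-homogenization metrics,
  population per-cycle averages, exact Wilcoxon / Mann–Whitney tests
  (enumeration at small n) and Kruskal–Wallis + Dunn.
- **`morphometry`** — Purkinje-cell soma/dendrite volumes from labeled
  serial sections (area × slice thickness, summed), dendrite/soma ratio.
- **`cli` / `reproduce`** — an `okrent` command tying the stages together
  with seeds and config hashes embedded in every artifact.

See `docs/methods.md` for the model, its calibration, and what the
synthetic data do and do not emulate.

## Worked example

Simulate a small cohort on the weak stimulus (profile 4: 4 °/s, 10 s
cycles) under the old-tadpole rule, then analyze it:

```sh
okrent simulate --profile 4 --n 8 --amplitude-mean 3.8 --amplitude-sd 1.8 \
    --slope -0.59 --setpoint 6.4 --residual-sd 0.5 --seed 11 --out demo
okrent analyze --traces demo --profile 4 --group old --seed 11 --out demo/results.json
```

`demo/` now holds one trace CSV per animal (time, stimulus angle, left and
right eye angle) plus the generator ground truth, and `results.json`
contains the per-animal summaries and the fitted regression:

```
slope             -0.613
x0                 6.2     (deg)
R2                 0.769
```

The recovered slope and setpoint sit near the generating values (−0.59,
6.4°): animals that started below 6.4° were pulled up, animals above were
pulled down, and `animal_000` (immediate 2.0°) gained 1.7° of response
amplitude over the session.  With only 8 animals the fit is noisy; the
seeded multi-replicate experiments below average it out.

`okrent reproduce` runs the full seeded cohort experiments (old, young and
climbing-fiber-transected groups at their study sample sizes n = 37, 28
and 15) and prints recovered slope, setpoint and R² per group next to the
generator's ground truth.

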