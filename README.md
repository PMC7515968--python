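# periquant

Quantification of perivascular tracer accumulation around cerebral vessels
from two-channel fluorescence time-lapse imaging.

## The problem

In experiments on perivascular (glymphatic) clearance, a fluorescently
labelled solute — typically soluble Aβ40 — is injected into cortex and
imaged by two-photon microscopy together with an intravascular red dye
(e.g. SR101) that fills vessel lumens. The readout is whether tracer
*compacts on the abluminal vessel wall* ("positive" vessels), how that
fraction evolves over the 40-minute session, how it depends on vessel
diameter and distance from the injection site, and — on fixed tissue —
how the vessel wall itself is composed. Calling vessels positive by eye is
subjective; `periquant` implements the line-profile statistic that makes
the call operational, plus everything needed to validate it on synthetic
scenes with known ground truth.

## The statistic

A 100 μm line is placed across each vessel. The lumen edge is the
half-maximum (FWHM) crossing of the red profile, taken as the 0 μm origin
of the abluminal axis. On the green channel,

    contrast = mean g over (0, 3] μm  −  mean g over (3, 10] μm
    z = contrast / σ̂,   σ̂ = 1.4826 · MAD of g over (15, 25] μm

and a vessel is positive when z, averaged over its two sides, is ≥ 3.
Tracer compacted on the wall raises the first 3 μm beyond the lumen above
the next 7 μm; diffuse background does not. Vessels whose profile cannot
be measured are excluded from every denominator. The same edge detection
yields FWHM lumen diameters; distance and time-course aggregation, animal
level averaging, Welch/Student t tests and Tukey-corrected two-way ANOVA
complete the chain, and a labelled-mask morphometry module measures wall
composition area fractions and abluminal basement-membrane thickness.

A full synthetic-scene generator (diffusing point source, erf-edged
lumens, trapezoidal wall-ring dynamics, Poisson × gain + Gaussian noise)
provides ground truth for every stage; see `docs/methods.md`.

## Worked example

```
periquant demo --out demo_out --seed 1
```

simulates a 20-vessel field over 9 frames, classifies every vessel on
every frame and aggregates. The run prints

```
INFO:periquant:simulate: 9 frames, 20 vessels (seed=1)
INFO:periquant:classify: 360 vessel-frame-side rows, 0 vessels fully excluded
INFO:periquant:metrics: peak positive fraction 45.0% at t=15 min
```

and `demo_out/stats_report.txt` contains

```
time course: argmax at t=15.0 min, plateau 15.0–30.0 min
diameters (um) at peak frame: positive: 9.660 ± 1.565 um vs negative: 9.560 ± 1.734 um; t(17.8) = 0.136, P = 0.8937 [ns]
```

Reading: the detected positive fraction rises over the first 15 minutes,
plateaus (here 15–30 min), and collapses as the wall signal decays; at the
peak frame the diameters of positive and negative vessels do not differ in
this small field (two-sided Welch t, p = 0.89). `demo_out/frame_summaries.csv`
holds the full time course — e.g. 10% positive at t = 0 (false calls on a
noise-only frame), 45% at the plateau against a 40%-true-positive draw, and
0% at t = 40 after decay — and `demo_out/results.csv` the per-vessel,
per-side window statistics.

The same stages are available as library calls (`periquant.simulate`,
`.profiles`, `.classify`, `.metrics`, `.morphometry`, `.stats`,
`.pipeline`) and as CLI subcommands (`simulate`, `classify`, `metrics`,
`morphometry`, `stats`, `run`, `demo`).

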