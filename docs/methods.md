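# Methods

`periquant` quantifies perivascular accumulation of a fluorescent tracer
(e.g. labelled Aβ40) around cerebral vessels in two-channel 2-D fluorescence
time-lapse images: a green tracer channel and a red intravascular-dye
channel that defines vessel lumens. This note documents the models,
conventions, parameter choices and known limitations.

## The classifying statistic

For each annotated vessel a 100 μm line is placed across the lumen at the
annotated orientation and both channels are sampled along it by bilinear
interpolation at 0.25 μm steps (about ⅓ pixel at the default resolution).
The lumen edge on each side is the half-maximum crossing of the red profile:
walking outward from the red maximum near the line centre, the edge is the
first position where red falls below

    background + 0.5 · (plateau − background),

linearly interpolated between samples, with `background` the median of the
outer 20% of samples on that side. The search for the plateau is restricted
to ±12 μm of the line centre so a brighter neighbouring lumen crossed by
the line cannot hijack the walk.

Each side's green profile is re-indexed so the abluminal axis starts at
0 μm at the detected edge. The statistic is the window contrast

    contrast = mean g over (0, 3] μm − mean g over (3, 10] μm,

i.e. tracer compacted onto the wall raises the first 3 μm above the next
7 μm. The contrast is standardized by a local noise scale — 1.4826·MAD of
green over the 15–25 μm abluminal annulus, beyond both the wall ring and
the steepest part of the diffusion gradient — giving `z_contrast`.

A vessel is called positive (default rule) when the mean of `z_contrast`
over its usable sides is ≥ 3. Sides are averaged, not OR-ed: the two sides
are treated as two measurements of one vessel. Two alternative modes exist
for sensitivity analysis: a near/far ratio rule (far mean floored at the
noise scale, threshold 1.2) and a one-sided paired test of near vs far
means across sides/frames (α = 0.01). Vessels with no usable side
("unclear profiles": truncated line, no lumen signal, open lumen) are
excluded from both numerator and denominator of every positive fraction.

The per-vessel z-rule is a design choice: expert calls validated only at
group level cannot be reproduced per vessel, so the operational definition
here is the standardized window contrast. The 50% (FWHM) edge criterion is
likewise adopted as the standard convention where the edge is otherwise
defined only pictorially.

## The synthetic scene

The generator emulates the imaging experiment the statistic was designed
for; its defaults are the study conditions and are not tuned per test.

* **Field**: 425.10 × 425.10 μm, 512 px (0.830 μm/px — the protocol states
  field size only, so pixel count is a choice). Frames at t = 0, 5, …, 40
  min. Single optical section; the classifying statistic is defined on a
  2-D line profile, so no 3-D rendering.
* **Vessels**: n = 50 per field (observed per-animal counts run ~43–54),
  diameters uniform on 5–13 μm (bracketing reported mean diameters
  5.092–12.795 μm), random orientation of the measuring line. Centres are
  rejection-sampled with ≥12 μm edge-to-edge clearance (so one vessel's
  analysis windows do not overlap another's wall ring) and a border margin
  of 50 μm + radius so the full measuring line always fits. Placement
  failure after a bounded number of attempts is a clear error, not a hang.
* **Tracer background**: free 2-D diffusion from a point source,
  C(r,t) = M/(4πDt)·exp(−r²/4Dt), with D = 10 μm²/min and M = 5000
  intensity·μm² — a visible but gentle gradient; no uptake or boundary
  terms, because the background's only role is to stress the classifier
  with a realistic non-flat baseline. At t = 0 the kernel is singular and
  the background is rendered as zero.
* **Red channel**: lumen disks at intensity 100, with the radial
  error-function edge profile I·Φ((r₀−r)/σ), σ = 0.5 μm — the analytic
  form of a half-micron Gaussian edge blur. Rendering the blur analytically
  keeps the half-maximum at exactly r₀, which is what makes sub-pixel FWHM
  diameter recovery possible on a 0.83 μm grid.
* **Wall ring**: truth-positive vessels carry a green annulus from the
  lumen edge to 3 μm out. Its amplitude follows a trapezoid: linear rise
  over 15 min, plateau 10 min, linear decay over 15 min (the simplest
  shape matching the observed rise/plateau/decay time course), peak
  amplitude 10 intensity units. Annulus edges are anti-aliased with a
  one-pixel-wide area-coverage ramp; hard pixel-centre edges would lose up
  to ~15% of the near-window mean depending on pixel phase, while the ramp
  makes the discretization loss deterministic (~px/8 per edge). The
  diffusing tracer is excluded (zeroed) inside lumens; the dye is confined
  to them.
* **Noise**: per pixel, Poisson(I/g)·g photon noise (gain g = 0.1) plus
  Gaussian read noise (SD 1), clipped at zero. The detector is not
  characterized in the protocol, so both parameters are config-exposed
  stand-ins. All randomness flows from a single config seed; frames are
  seeded by (seed, frame index), so datasets are byte-reproducible.

What the generator does **not** emulate: vessel curvature and elongation
(lumens are disks), pulsatility and diameter fluctuation, photobleaching,
z-drift, arterial/venous identity, spatially varying background other than
the source gradient. Passing tests therefore demonstrate correctness of the
measurement chain on known geometry, not robustness to every property of
real tissue.

## Numerical conventions

* Coordinates in μm, continuous; pixel i is centred at (i+0.5)·pixel_size;
  x rightwards, y downwards. All μm↔px conversion goes through
  `periquant.units`.
* All windows half-open: near (0, 3], far (3, 10], noise (15, 25].
* Profile sampling step 0.25 μm, required ≤ 1 pixel. Refining the step
  0.25→0.125 moves window means < 1% on smooth fields.
* Edge interpolation is linear between the two samples bracketing the
  threshold crossing. A side with < 10 μm of abluminal extent is unusable.
* Discretization of the window statistic: each annulus edge costs about
  pixel/8 of integrated near-window signal, i.e. ~7% of the ring amplitude
  at 0.83 μm/px but < 3% at 0.125 μm/px. Oracle tests of the statistic
  therefore run on a 128 μm / 1024 px scene; classification at the default
  resolution is unaffected (the z-rule operates at ~10× margins).
* Degenerate inputs: all-zero red → "no lumen signal"; red at plateau
  level through a line end → "open lumen" (distinguished from a dark tail
  by whether the tail median exceeds half the plateau); both-groups-constant
  t test → t = 0, p = 1, flagged; all-constant ANOVA → F = 0, p = 1.
* Wall-composition percentages are exact rationals (`fractions.Fraction`)
  on pixel counts, so the three classes sum to exactly 100.
* BM thickness casts 360 rays from the lumen centroid at ⅓-pixel radial
  steps; a ray contributes the run length of basement-membrane samples
  outward of the endothelium/intramural wall and reaching background; the
  result is the max over rays ("thickest region"), accurate to about one
  pixel on analytic annuli. Rays without an abluminal BM crossing are
  skipped; if none qualifies the vessel is unmeasurable and flagged.

## Aggregation and inference

The statistical unit is the animal: per-frame positive fractions and mean
diameters are averaged within an animal before any group comparison.
Pooling vessels across animals is available (`metrics.group_values` takes
any animal attribute) but is never the default, and tests demonstrate the
two conventions diverge on unbalanced data. The two-group test is Welch's
t by default (classical pooled Student t by flag); two-sided throughout.
Factorial comparisons use a type-II two-way ANOVA with Tukey-HSD-adjusted
pairwise cell contrasts (statsmodels). Stars: * p<0.05, ** p<0.01,
*** p<0.001; report format "mean ± SD" at three decimals.

## Problem sizes and a known power limit

Simulation-based checks use: 200 vessels (4 fields) for operating
characteristics, 1000 null vessels (20 fields) for false-positive
calibration, 200 repeats of a 5+5-animal experiment for effect detection,
and 10⁴ replicates for type-I calibration of the t test — sizes at which
every stage runs in seconds to a few minutes on one CPU.

One result deserves emphasis: with 50 vessels per animal and 5 animals per
group, the per-animal positive fraction carries binomial sampling noise of
~4–6.5 percentage points, and a two-sided test of 8% vs 30% at α = 0.001
then has ~63% power (Welch; ~84% pooled) even with a *perfect* classifier.
Detecting that contrast at α = 0.001 in ≥90% of experiments would need
roughly twice the vessels per animal. The acceptance suite measures this
rate honestly rather than tuning around it.

## Mask-based morphometry caveat

Wall composition and BM thickness operate on integer-labelled masks
(0 background, 1 lumen, 2 endothelium, 3 intramural cell, 4 basement
membrane). Producing such masks from micrographs (segmentation,
deconvolution) is out of scope; the `synthetic_wall_mask` generator
provides parametric annuli with sector perturbations for verification.
Perivascular spaces have no label code and are excluded by construction.
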