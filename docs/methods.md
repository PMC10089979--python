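# Methods

This note documents the models implemented in `tipm`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Stimulus protocols

The tonic protocol is a 5-s horizontal baseline followed by four 15-s
segments — nose-down hold, horizontal, nose-up hold, horizontal — at ±19°,
65 s in total. Each segment is opened by a 4-ms galvanometer step; the
step is modeled as occupying the first 4 ms of its segment, so the total
is exactly `baseline + 4·hold`. An `invert_order` flag swaps the
directions for order-control experiments. The impulse protocol delivers
two 10-ms there-and-back rotations (4 ms step, 2 ms eccentric hold, 4 ms
restoration) with onsets at 20 s and 50 s — the times at which the tonic
protocol's restoration steps occur — each followed by a 30-s horizontal
imaging window (total 80.01 s).

Epoch boundaries map to frame indices by `floor(time × frame_rate)`; the
"first second" of a response is the first `ceil(frame_rate)` frames
(3 frames at 3 frames/s two-photon, 5 volumes at 5 volumes/s volumetric).
This floor rule is applied everywhere so that window extraction is
bit-reproducible across acquisition rates.

## ΔF/F and classification

Baselines are phase-specific: the initial 5-s horizontal window for the
first-presented (nose-down) response; the last 3 s of the nose-down
response window for the nose-up response (responses can remain elevated,
so the immediately preceding window is the fair reference); and the 5 s
preceding the rotation for impulse responses. ΔF/F(t) = (F(t) − B)/B. A
non-positive baseline raises a typed error and the neuron is retained
with an exclusion code — never silently dropped.

Responsiveness is decided on **raw fluorescence**: the neuron is
responsive to a phase iff, in at least two trials, the mean raw F over
the first second of the response window is *strictly* more than two
baseline standard deviations above the baseline mean. The strict
inequality makes a perfectly flat trace (zero variance, zero response)
unresponsive rather than an error. Pattern labels operationalize manual
classification: `excitation` when the criterion holds;
`suppression_recovery` when the first 3 s dip at least 2 sd below
baseline and the final 5-s mean recovers above it; otherwise `none`.

The directionality index is computed on excitatory ΔF/F magnitudes
(first-second means, floored at 0 so suppression contributes nothing):
DI = (up − down)/(up + down), undefined (NaN) when both magnitudes are
zero. Subtype: nose-up iff DI > 0.1, nose-down iff DI < −0.1, otherwise
none; the threshold is strict, configurable, and corresponds to the
larger response exceeding the smaller by ≈22% (up/down = 11/9).

The coefficient of variation across repeats is sd/mean of the per-trial
first-second ΔF/F means, with population (n) normalization over the few
repeats. The method text this implements describes the ratio in the
opposite order (mean/sd), but the magnitudes reported alongside it
(~0.27) are only consistent with sd/mean; the literal reading is exposed
via `literal_cv=True`. The impulse residual is tonic(t) − impulse(t) on a
common window and the residual fraction is the ratio of first-second
means — the share of the tonic response not explained by the rapid step.

## Topography statistics

Coordinates: x rostrocaudal (rostral = 0), y mediolateral distance from
the midline (non-negative, so hemispheres pool without mirroring), z
dorsoventral (ventral = 0), all in μm at 4.8 px/μm; dorsoventral
subdivision index = floor(z / 5 μm) (a 40-μm stack → 8 planes).

Axis densities use 2-μm bins (below the ~5-μm soma diameter, stable under
resampling) and leave-one-neuron-out jackknife for the pointwise mean and
sd. The jackknife unit is the neuron; a fish-level resampling is obtained
by passing per-fish pooled populations.

The KS test is scipy's two-sided variant; one-sided statistics are
D⁺ = sup(F_a − F_b) (or D⁻) with the asymptotic Smirnov tail
p = exp(−2·n_eff·D²), replaced by the exact permutation distribution
(computed by lattice-path counting) when the pooled sample has ≤ 30
observations, where the asymptotic formula is off by a few percent.

MANOVA is one-way Wilks Λ from the between/within scatter matrices with
Rao's F approximation, exact for two groups (it then coincides with
Hotelling's T², verified in tests against an independently coded T² and
against statsmodels). The permutation chance null redraws the feature
labels uniformly with fixed label counts, leaves coordinates untouched,
and reruns the full battery per permutation (default 100), reporting the
per-permutation p list with mean ± sd. Pillai's trace was considered as a
robustness option and omitted: every population the pipeline feeds the
test is two-group, where the statistics coincide.

The optimal-sagittal-view search rotates the coordinate cloud over an
azimuth × elevation grid (azimuth about the dorsoventral axis, then
elevation about the mediolateral axis; default ±90° at 1°) and scores
each view by the **sum of the three per-axis KS D statistics** between
subtypes, with Fisher-combined p exposed as an alternative. Note a
property of this score: D is concave in the projected effect size, so the
sum is maximized by views that spread a separation *equally* across the
three axes — the optimum for a separation planted along direction
R(az₀, el₀)ᵀ·(1,1,1)/√3 is exactly (az₀, el₀), which is how planted-angle
recovery is tested. Transformed coordinates are display-only; every
statistic is computed on raw coordinates, and a test asserts the battery
is bitwise unaffected by running the search.

## Birthdating

born_before iff birth_hpf ≤ conversion time (inclusive boundary; missing
birth times are flagged). The cumulative birth curve reports per-fish
born-before fractions per conversion time with a least-squares slope and
R². Subtype proportions within a cohort use Wilson binomial intervals.
Emergence statistics are tie-corrected Kruskal–Wallis across timepoints
plus a pooled mature control, with Dunn's test against the control and
Holm correction (no multiple-comparison procedure is canonical here;
Dunn/Holm is the conventional rank-based choice and is recorded in the
output metadata). Comparisons are corrected within an axis; correcting
across axes as well is available by concatenating the pairwise tables.
Effect sizes are Cohen's d with the pooled (n−1) sd.

## Volumetric (oblique light-sheet) analysis

Per-pixel ΔF/F uses the trial's initial 15-s horizontal baseline and the
mean of the first 5 volumes of each direction's response window, averaged
across repeats; direction presentation order is randomized per trial and
carried as per-trial metadata, never assumed. Zero-baseline pixels are
masked NaN. The per-pixel DI reuses the ROI-level definition (verified by
a cross-module equivalence test); pseudocolor intensity is |DI| scaled to
the maximum |DI| within that pixel's sign class.

Geometric correction is a +90° rotation about the Y axis followed by the
fixed 4×4 shear

```
[[1, 0,      0, 0],
 [0, 0.707,  0, 0],
 [0, −0.707, 1, 0],
 [0, 0,      0, 1]]
```

acting on column homogeneous coordinates ordered (x, y, z, 1) — the axis
convention is a package decision, pinned by the example
(0, 1, 0, 1) → (0, 0.707, −0.707, 1) and a round-trip test (< 0.5 voxel).
Interpolation is linear with the output bounding box expanded to contain
the transformed volume. Because the shear has determinant 0.707 it
compresses volume, so the correct conservation law — and the one tested —
is that the voxel sum scales by |det| (within 1% for a smooth interior
blob); the raw sum itself cannot be preserved. Per-pixel statistics
default to raw (uncorrected) volumes, with correction applied for
display, mirroring the raw-coordinates rule for soma topography.

## Connectome tuning

Utricular afferent tuning is the synapse-count-weighted vector sum of its
hair cells' unit orientation vectors, normalized; it is invariant to
uniform count scaling. The vertical class requires |z-component| > 0.1 of
the vector norm (guards against sign flips from near-horizontal tuning;
configurable); below it, indeterminate. Canal afferent tuning follows
canal identity. The anterior/posterior ↔ nose-up/nose-down mapping is
stated both ways in the source literature; both conventions are exposed
(`results`: anterior → nose-up, the default, matching the figure
pseudocoloring; `methods`: the reverse) and neither is hard-coded as
correct. The match audit compares the count-weighted consensus class of
each input route per projection neuron; neurons missing a modality or
with indeterminate class are excluded with flags.

## Varicosity growth

Counts are normalized to percent of the class's mean count at 90 hpf
(the figure legend reads "maximum"; mean is the default, max selectable —
both anchors are exposed because the source is internally ambiguous).
The three-phase description (onset ~52–55 hpf, linear growth to ~78 hpf,
plateau) is operationalized as a least-squares piecewise model — 0 before
onset, linear to the plateau level, flat after — fitted by scanning
breakpoint pairs on a 1-hpf grid with the closed-form level solution per
pair; ties break toward the earliest onset. These outputs are model
estimates of a descriptive pattern, not source values. Timepoints are
compared by one-way ANOVA with Tukey HSD follow-ups.

## Synthetic-data generators (study conditions)

The generators' defaults are the study conditions every statistical test
runs under:

| parameter | default | basis |
|---|---|---|
| neurons/hemisphere | 37 ± 7 (Gaussian, rounded, ≥1) | reported census |
| subtype mix | 49% nose-up, 44% nose-down, 7% untuned | reported sample |
| cohort split | 65% early (22–30 hpf), 35% late (≥48 hpf) | 74/40 birthdated sample |
| subtype given cohort | early 96/4, late 25/75 (up/down) | reported cohort splits |
| true DI by subtype | up N(0.84, 0.28), down N(−0.73, 0.30), clipped | reported DI distributions |
| soma clusters | per-subtype isotropic 3-D Gaussians, sd 6 μm; up-mean (16, 10, 28) μm, down-mean (24, 18, 12) μm in a ~40-μm nucleus | dorsomedial vs ventrolateral clustering, partially overlapping ("roughly clustered", not laminar) |
| indicator kernel | difference of exponentials, rise τ 0.18 s, decay τ 1.8 s, steady-state-normalized | slow-indicator kinetics; no constants are published, so these are package defaults, configurable |
| noise | additive Gaussian on fluorescence, floored at 0 | simplest model satisfying non-negativity |
| baseline F | 100 a.u. | arbitrary scale (ΔF/F is scale-free; verified by test) |
| varicosity phases | onset 55 hpf, plateau 78 hpf; levels 30 (dorsal) / 10 (ventral) counts; Poisson noise | three-phase description; ~3× dorsal/ventral ratio |

The trial forward model drives a tuned firing rate during eccentric holds
(amplitudes gain·(1 ± DI)/2 for the two directions), adds impulse-locked
transients for impulse-responsive neurons and an optional
suppression-then-rebound pattern in the non-preferred direction (no
quantitative firing-rate model for suppression is published; the dip at
−0.5·gain with a 3-s +0.75·gain rebound is a modeling choice that
produces the qualitative pattern the classifier must detect), convolves
with the kernel, and floors at zero. Every generator draws from a named
substream of the single run seed (CRC-keyed `SeedSequence` spawn), so a
fixed seed gives bit-identical outputs and stages rerun reproducibly in
isolation.

What the generators do **not** emulate: optics (no point-spread function,
no photobleaching, no motion artifacts), ROI segmentation, registration
error, inter-fish variability beyond Poisson/Gaussian noise, and any
correlation structure between neurons. Passing tests therefore
demonstrate that the *analysis chain* is correct and calibrated under its
stated assumptions — not that those assumptions capture every property of
real recordings.

## Problem sizes and numerical choices

Monte-Carlo checks use 100–1000 seeds with per-seed sample sizes of
20–200 per group, chosen so each property is resolved well inside its
tolerance (e.g., type-I error 0.05 ± 0.02 over 1000 seeds has a binomial
sd of ~0.007). The permutation null defaults to 100 permutations. The
view-search default grid is ±90° × ±90° at 1°; examples and tests use
coarser grids, and the grid is fully configurable since the original
grid construction is not reconstructible. Degenerate inputs (zero
covariance, all-tied samples, zero baselines, zero-norm vector sums,
singular scatter matrices) are either handled with a defined value or
raise a typed error, as documented per function.

## Known limitations

- The pipeline consumes traced connectome graphs and varicosity counts;
  it performs no image segmentation or skeletonization.
- One-sided KS p-values are asymptotic above 30 pooled observations
  (conservative at moderate n).
- The MANOVA assumes non-singular within-group scatter; collinear
  coordinate data raises rather than regularizing.
- The three-phase growth fit assumes a zero pre-onset level in the
  normalized units; series with a nonzero floor need the floor subtracted
  first.
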