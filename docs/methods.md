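# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Extensibility ratio

The adhesion statistic for one segmented object is

ER = |1 − (4πS/p²)(L′/L″)|,

the product of the isoperimetric quotient (circularity) and the
moment-ellipse aspect ratio, subtracted from 1. Both factors are 1 for a
disk and tend to 0 for elongated, rough-boundary shapes, so ER ∈ [0, 1]
for continuous shapes, 0 meaning perfectly round. The sample statistic is
the arithmetic mean of ER over objects; both the pooled per-object mean and
per-image means are reported, since either aggregation is defensible and
they differ when object counts vary across images.

Conventions and numerical choices:

- **S** is the pixel count of the object.
- **p** is estimated with the 4-direction Crofton formula by default. The
  estimator matters: chain-code boundary length is anisotropic and biased
  high on diagonal edges, while Crofton converges to the true perimeter and
  is nearly rotation-invariant (measured ER of a 2:1 ellipse changes by
  <0.1% under rotation at semi-major axis 100 px, and agrees with the
  analytic ER to 0.3% at 50 px and 0.01% at 100 px). The chain-code
  estimator remains selectable for parity with classic region-props
  implementations; the estimator name is recorded in every measurement.
- **L′, L″** are the full axes 4√λ of the per-object pixel-coordinate
  covariance, with 1/12 added to each diagonal term — each pixel carries
  its own unit-square variance. This is the standard "ellipse with the same
  normalized second central moments" construction, and the correction keeps
  the minor axis positive even for one-pixel-wide objects.
- Degenerate objects (a single pixel, or any zero quantity) are rejected
  with an explicit error and counted as excluded during aggregation, never
  silently scored 0. They cannot occur after the 100-px area filter but are
  handled for direct library use.
- Discretization can push the factor product marginally past the
  continuous-shape bound of 1 (making ER slightly positive for a rasterized
  disk); products above 1.05 are flagged, and ER values above 1 (impossible
  for real estimates, defensively handled) are clamped with a counter.

## Image segmentation

The chain is binarize → fill holes → denoise → label → remove small
objects, in that order, each stage exposed separately:

- **Binarize**: Otsu's threshold by default (parameter-free; fails
  explicitly on constant images), or a fixed threshold; the threshold used
  is always reported. Foreground is intensity strictly above threshold.
- **Fill holes**: background regions not 4-connected to the image border
  become foreground (monotone and idempotent).
- **Denoise**: binary median filter, radius-1 disk (5-pixel cross) by
  default — removes isolated speckle of either polarity with minimal shape
  distortion.
- **Label**: 8-connected foreground components, labels in raster-scan order
  of first-encountered pixel (deterministic); background holes use the dual
  4-connectivity.
- **Small-object removal**: objects with area strictly below 100 px are
  dropped (an object of exactly 100 px survives); survivors are relabeled
  consecutively, order-preserving, pixel sets untouched.

Border-touching objects are retained by default with an opt-in exclusion
flag. Touching cells are not split (one connected component = one cell);
a watershed stage is deliberately out of scope.

## Recruitment kinematics

Directional displacement of a cell is the decrease of its distance to the
droplet center since its first sample; positive = toward the center.
Velocity at the evaluation time (default 14 h, the typical time-lapse
span) is cumulative displacement over elapsed time by default — bounded,
and well-defined from two samples — with a framewise mean-radial-step
alternative. Cohort means are arithmetic over cells, may be negative
(cells pushed away, e.g. by gel swelling), and per-cell values are kept for
group tests. Tracks with gaps are linearly interpolated across up to 2
missing frames and truncated at longer gaps; tracks starting exactly at
the center are excluded (direction undefined) and counted.

## Bead-referenced counting

With `B` beads spiked into the tube (volume × concentration; defaults
50 µl × 1.03×10⁶ /ml = 51 500) and `c`, `b` gated singlet cell and bead
events, the tube-level cell count is `c/b · B`. Because the instrument
samples cells and beads in proportion to abundance, the acquired fraction
cancels: stopping at an event cap (10⁴ events) does not bias the ratio.
Conditional on `c + b`, `c` is binomial, so a Clopper–Pearson interval on
`p = c/(c+b)` maps through `p/(1−p) · B` to a 99% CI on the count. Zero
bead events is an explicit failure (reference absent). The migration index
divides the count by the encapsulated-cell number; the volume chain
(trypsin + media dilution, loaded aliquot) is recorded in the counting
spec but cancels in the ratio.

Gating: a diagonal singlet band in FSC-H vs FSC-A first (slope estimated
as the median height/area ratio; band half-width 0.25 by default), then a
polygon gate for cells and an ellipse gate for beads in SSC-A vs FSC-A.
Gates are closed regions — boundary events count as inside, uniformly.
Gate coordinates are user-supplied configuration (as they would be drawn
in an acquisition software); a Gaussian-mixture auto-gate in log10 space
is provided for synthetic work, and every run logs the gate definitions
actually applied. The implemented order (singlet gate before population
gates) is a documented choice.

Known systematic: a doublet event carries two cells, so excluding doublets
undercounts cells by roughly the doublet fraction. The recovery benchmark
therefore uses a doublet-free tube, isolating the sampling/gating/CI
chain; doublet exclusion itself is verified by construction (10% planted
doublets ⇒ ~10% of cell events removed, ≥99% of doublets gone at the
default band).

## Material assays

Degradation records are paired dry weights (Wᵢ before, W_f after
enzymatic incubation, destructive sampling per timepoint). Two
percentages are always computed — weight lost `(Wᵢ−W_f)/Wᵢ·100` and
weight remaining `W_f/Wᵢ·100` — because the two are easily conflated in
reports; they sum to 100 by construction. Apparent mass gain (W_f > Wᵢ,
e.g. salt residue) is flagged, values still returned.

The relaxation timescale τ* is the first time stress falls to half its
initial value, by linear interpolation between the bracketing samples —
method-agnostic and convergent with sampling density; no constitutive
model is fitted. "Initial" is the first sample by default (step-strain
records peak at t = 0); a maximum-based definition is available. Records
that never reach the half level are reported right-censored at the record
end, not extrapolated. No smoothing is applied by default; an optional
moving median handles spiky rheometer traces. Noise-induced multiple
crossings use the first crossing, with the multiplicity reported. The
percent change of τ* vs a control, `100·(τ*_ctrl − τ*_treat)/τ*_ctrl`, is
positive when the treated gel relaxes faster.

## Group statistics

Two-tailed two-sample Student's t-test with pooled variance by default —
matching the ubiquitous spreadsheet default for triplicate assay data —
with Welch's variant by flag (triplicate variances are rarely equal;
pooled is kept as default only for comparability). Significance at
α = 0.05, no multiple-testing correction by default; a Holm step-down
helper is available. Two all-constant groups with equal means return
p = 1 by convention (noted in the result) rather than NaN.

## Synthetic-data generator

Every input class has a generator with analytically known truth, all
deterministic under a single spec-level seed via `SeedSequence` spawning
in fixed order (identical spec + seed ⇒ bit-identical output):

- **Images**: elliptical cells (pixel center inside ellipse ⇒ pixel
  belongs; unambiguous and consistent with area counting) of constant
  intensity on a uniform background, additive Gaussian noise clipped at 0.
  Truth: S = πab, perimeter by the complete elliptic integral 4aE(e),
  axes 2b/2a. Cells must be pairwise disjoint. Default pixel size
  0.5 µm/px (typical confocal scale; arbitrary but fixed). Not emulated:
  point-spread blur, depth attenuation, intensity texture, touching
  cells, 3D stacks — so passing tests show the measurement chain is
  correct on its own model, not that segmentation is robust to real
  confocal artifacts.
- **Tracks**: per frame, a drift step of `drift_speed·dt` toward the
  center (capped at reaching it) plus an isotropic Gaussian step
  (`step_sd` per axis). `n_frames` counts motion intervals; tracks carry
  `n_frames+1` samples at t = 0…n_frames·dt, so 14 one-hour frames end at
  the canonical 14 h evaluation point. Initial positions uniform in angle
  and radius (default 300–500 µm, far enough that diffusion's radial
  curvature bias is negligible against 3·SEM). Not emulated: collisions,
  confinement, swelling-induced advection.
- **Events**: three bivariate-normal populations in (FSC-A, SSC-A) —
  fibroblast-like (high FSC-A), bead-like (high SSC-A, low FSC-A),
  debris (low/low), clipped at 0; FSC-H = FSC-A·(1+ε), ε ~ N(0, 0.03)
  for singlets; a doublet doubles FSC-A and keeps FSC-H (pulse-geometry
  rationale), default doublet fraction 0. Rows shuffled.
- **Relaxation**: σ(t) = σ₀e^(−t/τ) + Gaussian noise; default grid 0–3 h
  at 10 s, matching a typical rheometer record.
- **Degradation**: two-phase exponential (fast rate to a breakpoint day,
  default day 7, slow rate after), Gaussian noise, floored at 0,
  triplicates per day at days 0, 1, 3, 7, 14, 30. The two-phase form is a
  fixture reproducing the fast-first-week/late-plateau shape, not a
  kinetic model claim.

## Study runner and problem sizes

`run_study` derives per-group, per-assay, per-replicate seeds from the
global seed by ordered `SeedSequence` spawning, executes the configured
assays, compares each group to the control per assay, and serializes a
report with provenance (config hash, seed, version). Reports use sorted
keys so reruns are byte-identical.

Verification problem sizes were chosen as the smallest at which the
statistical checks are well-powered: 500 cells for random-walk nulls, 200
for drift recovery, 100 seeded acquisitions of 10⁴ events for counting
coverage, 10⁴ replicates for t-test calibration, rasterization checks at
semi-major axes 12.5–200 px.

## Limitations

- The segmentation chain assumes one cell per connected component; dense
  cultures with touching cells would need a splitting stage.
- ER compares shapes only; intensity information is discarded after
  thresholding.
- The counting estimator inherits the doublet undercount described above
  and assumes beads and cells are acquired with equal efficiency.
- FCS file ingestion is not implemented; event tables are CSV.
- The generators' Gaussian noise models are deliberately simple; none of
  the tests here certify performance on real instrument noise.
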