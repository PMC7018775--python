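# gelcontact

Quantitative analysis of cell–hydrogel interaction for soft-biomaterials
work: how well do cells adhere to, get recruited by, and migrate through a
hydrogel formulation? The package implements the measurement side of a
typical formulation-screening study — e.g. a glycol-chitosan gel doped with
increasing carbon-nanotube concentrations — as a tested, reusable pipeline
with a synthetic-data generator so every stage can be validated against
known ground truth without microscope or cytometer data.

## What it computes

**Cell adhesion — the extensibility ratio (ER).** F-actin confocal images
are segmented (binarize → fill holes → median denoise → label 8-connected
components → drop objects under 100 px), and each cell object is scored by

```
ER = | 1 − (4πS/p²) · (L′/L″) |
```

where `S` is the object's area, `p` its perimeter, and `L′`, `L″` the minor
and major full axes of the ellipse with the same normalized second central
moments as the object. Both factors equal 1 for a circle, so a round
(non-adherent) cell scores 0, while an elongated, rough-edged (adherent,
spread) cell approaches 1. The mean ER over a sample's objects is the
adhesion statistic. Perimeter uses the near-isotropic 4-direction Crofton
estimator by default (chain-code selectable); axes are `4√λ` of the
pixel-coordinate covariance with the 1/12 per-pixel variance correction.

**Cell recruitment — directional kinematics.** From time-lapse cell tracks
around a hydrogel droplet, the directional displacement
`d(t) = ‖p(t₀) − c‖ − ‖p(t) − c‖` (positive toward the droplet center `c`)
and the directional velocity `d(t_eval)/(t_eval − t₀)` at the end of the
recording (default 14 h), averaged over the cohort.

**Cell migration — bead-referenced counting.** Transwell-migrated cells are
counted absolutely on a cytometer by spiking a known number of counting
beads (50 µl × 1.03×10⁶ particles/ml = 51 500 beads): after a diagonal
FSC-H/FSC-A singlet gate and polygon/ellipse population gates,
`cells = (cell events / bead events) × beads spiked`, with a 99%
Poisson-ratio (Clopper–Pearson) confidence interval. The migration index is
that count divided by the cells originally encapsulated.

**Material assays.** Enzymatic degradation from paired dry weights — both
`(Wᵢ − W_f)/Wᵢ × 100` (weight lost) and `W_f/Wᵢ × 100` (weight remaining)
are always reported — and the stress-relaxation timescale τ*: the first
time the stress under constant strain falls to half its initial value
(linear interpolation; right-censored if never reached). For an exponential
decay, τ* = τ ln 2.

**Group statistics.** Two-tailed two-sample Student's t-test (Welch
optional) at α = 0.05, plus a reproducible multi-group study runner that
emits a deterministic JSON report (same config + seed ⇒ byte-identical).

## Worked example

```python
import numpy as np
from gelcontact import synthetic_data as sd, segmentation as seg, morphometrics as mm
from gelcontact.material import relaxation_timescale

# five elongated cells (25:12 px ellipses, random orientations) on a noisy background
cells = tuple(
    sd.EllipseCell(center=(90 + 160 * i, 90), a=25, b=12, orientation=th)
    for i, th in enumerate(np.random.default_rng(7).uniform(0, np.pi, 5))
)
spec = sd.SyntheticImageSpec(width=840, height=180, cells=cells,
                             background_intensity=20, noise_sd=5, seed=11)
rendered = sd.render_image(spec)

labeled, report = seg.segment(seg.RawImage(rendered.image))
result = mm.aggregate_er(mm.measure_all(labeled))
print(f"objects recovered: {labeled.n_objects} (threshold {report['threshold']:.1f})")
print(f"mean ER: {result.mean_er:.4f}  (analytic ER of a 25:12 ellipse: {mm.analytic_er(25, 12):.4f})")

curve = sd.simulate_relaxation(sd.RelaxSimSpec(sigma0=100, tau=1000, noise_sd=0.5, seed=3))
res = relaxation_timescale(curve["t_s"], curve["sigma"])
print(f"tau* = {res.tau_star:.1f} s  (tau ln 2 = {1000 * np.log(2):.1f} s)")
```

prints

```
objects recovered: 5 (threshold 44.2)
mean ER: 0.6007  (analytic ER of a 25:12 ellipse: 0.6043)
tau* = 675.7 s  (tau ln 2 = 693.1 s)
```

All five planted cells are recovered by Otsu thresholding; their pooled
mean ER sits within 0.6% of the closed-form value for that cell shape, and
the half-stress time of a noisy τ = 1000 s exponential lands near τ ln 2.

The same stages are available from the shell:

```sh
gelcontact simulate image --config cells.yaml --seed 1 --out img.tif
gelcontact segment img.tif --out labels.tif --report report.json
gelcontact morphometry labels.tif --out per_object.csv --summary summary.json
gelcontact count events.csv --spec counting.yaml --out counts.json
gelcontact run --config study.yaml --seed 7 --out-dir results/
```

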