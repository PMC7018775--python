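"""Synthetic inputs with analytically known ground truth.

Every input class the analysis pipeline consumes can be generated here:

- fluorescence micrographs of elliptical F-actin-stained cell bodies on a
  noisy background (:func:`render_image`),
- random-walk cell tracks with optional drift toward a droplet center
  (:func:`simulate_tracks`),
- three-population cytometry event clouds — cells, counting beads, debris —
  with a doublet fraction (:func:`simulate_events`),
- exponential stress-relaxation curves (:func:`simulate_relaxation`),
- two-phase enzymatic weight-loss series (:func:`simulate_degradation`).

All generators are deterministic under their spec's seed: the spec-level
seed feeds a single :class:`numpy.random.SeedSequence`, and independent
sub-streams are spawned from it in a fixed order, so identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe

__all__ = [
    "EllipseCell",
    "SyntheticImageSpec",
    "TrackSimSpec",
    "EventSimSpec",
    "RelaxSimSpec",
    "DegradationSimSpec",
    "SyntheticImage",
    "render_image",
    "simulate_tracks",
    "simulate_events",
    "simulate_relaxation",
    "simulate_degradation",
    "ellipse_perimeter",
    "write_image_tiff",
]


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact perimeter of an ellipse with semi-axes ``a >= b``.

    Uses the complete elliptic integral of the second kind:
    ``p = 4 a E(e)`` with eccentricity ``e = sqrt(1 - b^2/a^2)``.
    """
    if not a >= b > 0:
        raise ValueError(f"require a >= b > 0, got a={a}, b={b}")
    m = 1.0 - (b / a) ** 2  # scipy's ellipe takes the parameter m = e^2
    return float(4.0 * a * ellipe(m))


@dataclass(frozen=True)
class EllipseCell:
    """An elliptical fluorescent cell body.

    center : (x, y) in pixels; a, b : semi-major/minor axes in pixels;
    orientation : radians, CCW from the +x axis; intensity : grey levels.
    """

    center: tuple[float, float]
    a: float
    b: float
    orientation: float = 0.0
    intensity: float = 180.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        """Analytic area pi*a*b in px^2."""
        return float(np.pi * self.a * self.b)

    @property
    def perimeter(self) -> float:
        """Analytic perimeter via the complete elliptic integral, in px."""
        return ellipse_perimeter(self.a, self.b)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a synthetic single-channel fluorescence micrograph."""

    width: int = 512
    height: int = 512
    pixel_size: float = 0.5  # um/px; confocal default, arbitrary but fixed
    cells: tuple[EllipseCell, ...] = ()
    background_intensity: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("image must be at least 32x32 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "cells", tuple(self.cells))
        for c in self.cells:
            x, y = c.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"cell center {c.center} outside image bounds")


@dataclass(frozen=True)
class SyntheticImage:
    """A rendered micrograph plus its ground truth.

    ``truth`` holds one analytic morphology record per cell, in label order,
    with the quantities the extensibility ratio needs: area S = pi*a*b,
    elliptic-integral perimeter p, minor/major full axes 2b and 2a.
    """

    image: np.ndarray  # float64 grey levels, clipped at 0
    truth_labels: np.ndarray  # int32; 0 background, 1..n cells
    truth: tuple[dict, ...]


def _ellipse_mask(
    cell: EllipseCell, width: int, height: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-center rasterization of one ellipse; returns rows, cols, mask."""
    cx, cy = cell.center
    pad = cell.a + 1.0
    r0 = max(0, int(np.floor(cy - pad)))
    r1 = min(height, int(np.ceil(cy + pad)) + 1)
    c0 = max(0, int(np.floor(cx - pad)))
    c1 = min(width, int(np.ceil(cx + pad)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    ct, st = np.cos(cell.orientation), np.sin(cell.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / cell.a) ** 2 + (v / cell.b) ** 2 <= 1.0
    return rr[inside], cc[inside], inside


def render_image(spec: SyntheticImageSpec) -> SyntheticImage:
    """Render non-overlapping elliptical cells onto a noisy background.

    A pixel belongs to a cell iff its center lies inside the ellipse. Cells
    must be pairwise non-overlapping at pixel resolution; overlap is a
    rejection, not a silent merge, because the downstream pipeline treats
    each connected component as one cell.
    """
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    image = np.full((spec.height, spec.width), spec.background_intensity, dtype=float)
    truth = []
    for i, cell in enumerate(spec.cells, start=1):
        rows, cols, _ = _ellipse_mask(cell, spec.width, spec.height)
        if rows.size and labels[rows, cols].any():
            other = int(labels[rows, cols].max())
            raise ValueError(
                f"cells {other} and {i} overlap at pixel resolution; "
                "synthetic cells must be pairwise disjoint"
            )
        labels[rows, cols] = i
        image[rows, cols] = cell.intensity
        truth.append(
            {
                "label": i,
                "area": cell.area,
                "perimeter": cell.perimeter,
                "minor_axis": 2.0 * cell.b,
                "major_axis": 2.0 * cell.a,
                "centroid": (cell.center[1], cell.center[0]),  # (row, col)
            }
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)
    return SyntheticImage(image=image, truth_labels=labels, truth=tuple(truth))


def write_image_tiff(path, image: np.ndarray) -> None:
    """Write a grey-level image as 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.clip(np.round(image), 0, 65535).astype(np.uint16))


# ---------------------------------------------------------------------------
# cell tracks


@dataclass(frozen=True)
class TrackSimSpec:
    """Random-walk cell tracks with optional drift toward a droplet center.

    ``n_frames`` counts motion intervals: each track has ``n_frames + 1``
    samples at t = 0, dt, ..., n_frames*dt. ``drift_speed`` is signed;
    positive means toward the center (um/hour). ``step_sd`` is the isotropic
    per-frame Gaussian step (um per coordinate axis).
    """

    n_cells: int = 100
    n_frames: int = 14
    dt: float = 1.0  # hours
    step_sd: float = 5.0  # um
    drift_speed: float = 0.0  # um/hour, + = toward center
    center: tuple[float, float] = (0.0, 0.0)
    initial_radius_range: tuple[float, float] = (300.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        lo, hi = self.initial_radius_range
        if not (0 < lo <= hi):
            raise ValueError("initial radii must be positive and ordered")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")


def simulate_tracks(spec: TrackSimSpec) -> pd.DataFrame:
    """Simulate tracks; returns tidy frame (cell_id, t_hours, x_um, y_um).

    Per frame each cell moves ``drift_speed * dt`` along the unit vector
    toward the center — capped so a cell never overshoots the center in a
    single drift move — plus an isotropic Gaussian step of sd ``step_sd``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_init, rng_steps = (np.random.default_rng(s) for s in ss.spawn(2))
    n, m = spec.n_cells, spec.n_frames
    center = np.asarray(spec.center, dtype=float)

    radii = rng_init.uniform(*spec.initial_radius_range, size=n)
    angles = rng_init.uniform(0.0, 2.0 * np.pi, size=n)
    pos = center + radii[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])

    steps = rng_steps.normal(0.0, spec.step_sd, size=(m, n, 2)) if spec.step_sd > 0 else np.zeros((m, n, 2))
    drift_len = spec.drift_speed * spec.dt

    positions = np.empty((m + 1, n, 2))
    positions[0] = pos
    for k in range(m):
        to_center = center - pos
        dist = np.linalg.norm(to_center, axis=1)
        move = np.zeros_like(pos)
        nz = dist > 0
        # cap: a positive drift move never carries a cell past the center
        step = np.clip(np.full(nz.sum(), drift_len), None, dist[nz])
        move[nz] = to_center[nz] / dist[nz, None] * step[:, None]
        pos = pos + move + steps[k]
        positions[k + 1] = pos

    t = np.arange(m + 1) * spec.dt
    return pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), m + 1),
            "t_hours": np.tile(t, n),
            "x_um": positions[:, :, 0].T.ravel(),
            "y_um": positions[:, :, 1].T.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# cytometry events


@dataclass(frozen=True)
class EventSimSpec:
    """Three-population cytometry event cloud over (FSC-A, SSC-A).

    Defaults emulate the assay geometry: counting beads sit at high SSC-A /
    low FSC-A, fibroblasts at high FSC-A / lower SSC-A, debris at low/low.
    Singlets have FSC-H proportional to FSC-A (small multiplicative noise);
    a doublet's FSC-A is doubled while its FSC-H is not, the pulse-geometry
    basis of FSC-H vs FSC-A singlet gating.
    """

    n_cells: int = 5000
    n_beads: int = 4000
    n_debris: int = 1000
    cell_mean: tuple[float, float] = (150_000.0, 40_000.0)
    cell_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (15_000.0**2, 0.0),
        (0.0, 8_000.0**2),
    )
    bead_mean: tuple[float, float] = (30_000.0, 120_000.0)
    bead_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (3_000.0**2, 0.0),
        (0.0, 10_000.0**2),
    )
    debris_mean: tuple[float, float] = (8_000.0, 6_000.0)
    debris_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (3_000.0**2, 0.0),
        (0.0, 2_500.0**2),
    )
    doublet_fraction: float = 0.0
    fsch_noise_sd: float = 0.03  # multiplicative sd of FSC-H about FSC-A
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_beads", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.doublet_fraction < 1):
            raise ValueError("doublet_fraction must be in [0, 1)")
        for name in ("cell_cov", "bead_cov", "debris_cov"):
            cov = np.asarray(getattr(self, name), dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be a symmetric 2x2 matrix")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"{name} must be positive-definite")


def simulate_events(spec: EventSimSpec) -> pd.DataFrame:
    """Draw the event table; true population labels ride along for testing.

    Returns columns event_id, FSC_A, SSC_A, FSC_H, true_label
    ('cell' | 'bead' | 'debris'), is_doublet. Channel values are clipped
    at 0 (non-negative linear units). Row order is shuffled so acquisition
    order carries no population information.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_pop, rng_doublet, rng_h, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(4))

    parts = []
    for label, n, mean, cov in (
        ("cell", spec.n_cells, spec.cell_mean, spec.cell_cov),
        ("bead", spec.n_beads, spec.bead_mean, spec.bead_cov),
        ("debris", spec.n_debris, spec.debris_mean, spec.debris_cov),
    ):
        xy = rng_pop.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=n)
        df = pd.DataFrame({"FSC_A": xy[:, 0], "SSC_A": xy[:, 1]})
        df["true_label"] = label
        parts.append(df)
    events = pd.concat(parts, ignore_index=True)

    events["FSC_H"] = events["FSC_A"] * (
        1.0 + rng_h.normal(0.0, spec.fsch_noise_sd, size=len(events))
    )
    is_doublet = np.zeros(len(events), dtype=bool)
    cell_idx = np.flatnonzero(events["true_label"].to_numpy() == "cell")
    if spec.doublet_fraction > 0 and cell_idx.size:
        n_doublets = int(round(spec.doublet_fraction * cell_idx.size))
        chosen = rng_doublet.choice(cell_idx, size=n_doublets, replace=False)
        # doubled area, unchanged height
        events.loc[chosen, "FSC_A"] *= 2.0
        is_doublet[chosen] = True
    events["is_doublet"] = is_doublet

    for ch in ("FSC_A", "SSC_A", "FSC_H"):
        events[ch] = events[ch].clip(lower=0.0)

    events = events.iloc[rng_shuffle.permutation(len(events))].reset_index(drop=True)
    events.insert(0, "event_id", np.arange(len(events)))
    return events[["event_id", "FSC_A", "SSC_A", "FSC_H", "true_label", "is_doublet"]]


# ---------------------------------------------------------------------------
# stress relaxation


@dataclass(frozen=True)
class RelaxSimSpec:
    """Exponential stress decay sigma(t) = sigma0 * exp(-t/tau) + noise."""

    sigma0: float = 100.0
    tau: float = 1000.0  # seconds
    times: tuple[float, ...] = field(default_factory=lambda: tuple(np.arange(0.0, 10801.0, 10.0)))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.tau <= 0:
            raise ValueError("sigma0 and tau must be > 0")
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        object.__setattr__(self, "times", tuple(t))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_relaxation(spec: RelaxSimSpec) -> pd.DataFrame:
    """Return (t_s, sigma) samples of the noisy exponential decay."""
    t = np.asarray(spec.times, dtype=float)
    sigma = spec.sigma0 * np.exp(-t / spec.tau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        sigma = sigma + rng.normal(0.0, spec.noise_sd, size=t.size)
    return pd.DataFrame({"t_s": t, "sigma": sigma})


# ---------------------------------------------------------------------------
# enzymatic degradation


@dataclass(frozen=True)
class DegradationSimSpec:
    """Two-phase exponential dry-weight loss under enzymatic degradation.

    W_f(day) = Wi * exp(-fast_rate * min(day, breakpoint_day))
                  * exp(-slow_rate * max(0, day - breakpoint_day)) + noise,
    floored at 0. The two-phase form reproduces the qualitative fast-first-
    week / late-plateau shape of lysozyme degradation series; it is a test
    fixture, not a kinetic model claim.
    """

    Wi: float = 10.0  # mg
    fast_rate: float = 0.05  # per day
    slow_rate: float = 0.005  # per day
    breakpoint_day: float = 7.0
    measurement_days: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0, 14.0, 30.0)
    noise_sd: float = 0.0  # mg
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Wi <= 0:
            raise ValueError("Wi must be > 0")
        if self.fast_rate < 0 or self.slow_rate < 0:
            raise ValueError("rates must be >= 0")
        d = np.asarray(self.measurement_days, dtype=float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("measurement_days must be non-negative and increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def degradation_curve(spec: DegradationSimSpec, day: np.ndarray | float) -> np.ndarray | float:
    """Noise-free W_f at the given day(s), in mg."""
    day = np.asarray(day, dtype=float)
    fast = np.minimum(day, spec.breakpoint_day)
    slow = np.maximum(0.0, day - spec.breakpoint_day)
    return spec.Wi * np.exp(-spec.fast_rate * fast - spec.slow_rate * slow)


def simulate_degradation(spec: DegradationSimSpec) -> pd.DataFrame:
    """Paired dry weights per sampled day and replicate.

    Returns columns sample_id, day, Wi_mg, Wf_mg; one destructively sampled
    specimen per (day, replicate), as in a sacrifice-per-timepoint design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    for day in spec.measurement_days:
        wf_clean = float(degradation_curve(spec, day))
        for rep in range(spec.n_replicates):
            wf = wf_clean + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            rows.append(
                {
                    "sample_id": f"d{day:g}_r{rep + 1}",
                    "day": day,
                    "Wi_mg": spec.Wi,
                    "Wf_mg": max(0.0, wf),
                }
            )
    return pd.DataFrame(rows)
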