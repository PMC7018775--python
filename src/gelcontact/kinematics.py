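"""Directional kinematics of cells recruited toward a hydrogel droplet.

In a radial recruitment assay, cells seeded around a hydrogel droplet may
move toward it (attraction) or away (e.g. pushed back by gel swelling).
The directional displacement of a cell at time t is the decrease of its
distance to the droplet center since its first sample:

    d(t) = ||p(t0) - c|| - ||p(t) - c||

so positive d means motion toward the center. The directional velocity at
an evaluation time (typically the end of a 14-hour time-lapse) is, under
the default *cumulative* convention, d(t_eval)/(t_eval - t0); the
*framewise* convention averages per-frame radial steps over frame
durations instead. Cohort means may legitimately be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "DropletGeometry",
    "KinematicsResult",
    "TrackAtCenterError",
    "tracks_from_dataframe",
    "directional_displacement",
    "directional_velocity",
    "cohort_summary",
]


class TrackAtCenterError(ValueError):
    """The track starts exactly at the droplet center: direction undefined."""


@dataclass(frozen=True)
class Track:
    """Time-stamped positions of one cell (times strictly increasing, um)."""

    cell_id: int | str
    t: np.ndarray  # hours
    xy: np.ndarray  # (n, 2) um

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if xy.shape != (t.size, 2):
            raise ValueError("xy must be (n_samples, 2)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)


@dataclass(frozen=True)
class DropletGeometry:
    """Reference center of the hydrogel droplet (um); radius for reporting."""

    center: tuple[float, float]
    radius: float | None = None


@dataclass(frozen=True)
class KinematicsResult:
    """Cohort kinematics at the evaluation time."""

    t_eval: float
    per_cell_displacement: tuple[float, ...]  # um, order matches cell_ids
    per_cell_velocity: tuple[float, ...]  # um/h (cumulative convention)
    cell_ids: tuple
    mean_displacement: float
    mean_velocity: float
    sem_displacement: float
    sem_velocity: float
    n_cells: int
    n_excluded: int
    mean_series_t: tuple[float, ...]  # cohort mean displacement over time
    mean_series_d: tuple[float, ...]


def tracks_from_dataframe(
    df: pd.DataFrame, max_gap_frames: int = 2, dt: float | None = None
) -> list[Track]:
    """Build tracks from a tidy (cell_id, t_hours, x_um, y_um) frame.

    Tracking gaps are standard hygiene: if a cell misses grid timepoints
    that other cells have, runs of up to ``max_gap_frames`` missing frames
    are linearly interpolated; at a longer gap the track is truncated. The
    frame interval is inferred from the data unless ``dt`` is given.
    """
    grid = np.unique(df["t_hours"].to_numpy(dtype=float))
    if dt is None and grid.size > 1:
        dt = float(np.min(np.diff(grid)))
    tracks = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("t_hours")
        t = g["t_hours"].to_numpy(dtype=float)
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if dt is not None and t.size >= 2:
            n_missing = np.round(np.diff(t) / dt).astype(int) - 1
            if np.any(n_missing > max_gap_frames):
                cut = int(np.argmax(n_missing > max_gap_frames)) + 1
                t, xy = t[:cut], xy[:cut]
                n_missing = n_missing[: cut - 1]
            if np.any(n_missing > 0):
                full_t = np.arange(t[0], t[-1] + dt / 2, dt)
                xy = np.column_stack(
                    [np.interp(full_t, t, xy[:, 0]), np.interp(full_t, t, xy[:, 1])]
                )
                t = full_t
        if t.size >= 2:
            tracks.append(Track(cell_id=cid, t=t, xy=xy))
    return tracks


def _distances(track: Track, geom: DropletGeometry) -> np.ndarray:
    return np.linalg.norm(track.xy - np.asarray(geom.center, dtype=float), axis=1)


def directional_displacement(track: Track, geom: DropletGeometry) -> tuple[np.ndarray, np.ndarray]:
    """d(t) = initial distance to center minus current distance; d(t0) = 0."""
    r = _distances(track, geom)
    if r[0] <= 1e-12:
        raise TrackAtCenterError(
            f"track {track.cell_id!r} starts at the droplet center; direction undefined"
        )
    return track.t.copy(), r[0] - r


def directional_velocity(
    track: Track,
    geom: DropletGeometry,
    t_eval: float,
    convention: str = "cumulative",
) -> float:
    """Directional velocity (um/h) at ``t_eval``.

    cumulative: d(t_eval) / (t_eval - t0), with d linearly interpolated
    between samples. framewise: mean of per-frame radial steps divided by
    their frame durations, over frames up to ``t_eval``.
    """
    t, d = directional_displacement(track, geom)
    if not (t[0] < t_eval <= t[-1]):
        raise ValueError(
            f"t_eval={t_eval} outside track span ({t[0]}, {t[-1]}] for cell {track.cell_id!r}"
        )
    if convention == "cumulative":
        return float(np.interp(t_eval, t, d) / (t_eval - t[0]))
    if convention == "framewise":
        sel = t <= t_eval + 1e-12
        tt, dd = t[sel], d[sel]
        return float(np.mean(np.diff(dd) / np.diff(tt)))
    raise ValueError(f"unknown velocity convention {convention!r}")


def cohort_summary(
    tracks: list[Track], geom: DropletGeometry, t_eval: float
) -> KinematicsResult:
    """Per-cell displacement and velocity at ``t_eval``, averaged arithmetically.

    Tracks that do not span ``t_eval`` or start at the center are excluded
    and counted. Per-cell values are retained for group statistics; the
    cohort mean displacement series is computed over the timepoints shared
    by all usable tracks.
    """
    disp, vel, ids = [], [], []
    series = []
    n_excluded = 0
    for tr in tracks:
        try:
            t, d = directional_displacement(tr, geom)
            if not (t[0] < t_eval <= t[-1]):
                n_excluded += 1
                continue
            disp.append(float(np.interp(t_eval, t, d)))
            vel.append(float(np.interp(t_eval, t, d) / (t_eval - t[0])))
            ids.append(tr.cell_id)
            series.append((t, d))
        except TrackAtCenterError:
            n_excluded += 1
    if not disp:
        raise ValueError(f"no usable track spans t_eval={t_eval}")

    common_t = series[0][0]
    for t, _ in series[1:]:
        common_t = np.intersect1d(common_t, t)
    mean_d = np.mean(
        [np.interp(common_t, t, d) for t, d in series], axis=0
    ) if common_t.size else np.zeros(0)

    disp_arr = np.asarray(disp)
    vel_arr = np.asarray(vel)
    n = disp_arr.size
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return KinematicsResult(
        t_eval=float(t_eval),
        per_cell_displacement=tuple(disp),
        per_cell_velocity=tuple(vel),
        cell_ids=tuple(ids),
        mean_displacement=float(disp_arr.mean()),
        mean_velocity=float(vel_arr.mean()),
        sem_displacement=sem(disp_arr),
        sem_velocity=sem(vel_arr),
        n_cells=n,
        n_excluded=n_excluded,
        mean_series_t=tuple(np.asarray(common_t, dtype=float)),
        mean_series_d=tuple(np.asarray(mean_d, dtype=float)),
    )
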