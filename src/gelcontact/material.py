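"""Hydrogel material assays: enzymatic degradation and stress relaxation.

Degradation is summarized from paired lyophilized dry weights (initial
W_i, final W_f). Two complementary percentages are always reported:

    loss_percent      = (W_i - W_f) / W_i * 100
    remaining_percent = W_f / W_i * 100

They sum to 100; reporting both avoids the classic ambiguity between "the
sample lost 30%" and "the sample degraded to 70% of its weight". A final
weight above the initial one (possible salt residue) is flagged, with the
values still returned.

Stress relaxation under constant strain is reduced to the relaxation
timescale tau*: the first time the stress falls to one-half of its
initial value, found by linear interpolation between the bracketing
samples. For a pure exponential sigma0*exp(-t/tau) this gives
tau* = tau*ln(2). The initial value is the first recorded sample by
default (step-strain records peak at t = 0); the maximum can be chosen
instead. If the record ends before the half level is reached, the result
is right-censored at the record end rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegradationRecord",
    "WeightChange",
    "RelaxationResult",
    "percent_weight_change",
    "degradation_table",
    "relaxation_timescale",
    "relative_tau_change",
]


@dataclass(frozen=True)
class DegradationRecord:
    """Paired dry weights of one sample at one timepoint."""

    sample_id: str
    day: float
    Wi: float  # mg
    Wf: float  # mg

    def __post_init__(self) -> None:
        if self.Wi <= 0:
            raise ValueError("Wi must be > 0")
        if self.Wf < 0:
            raise ValueError("Wf must be >= 0")


@dataclass(frozen=True)
class WeightChange:
    loss_percent: float
    remaining_percent: float
    mass_gain_flagged: bool = False


def percent_weight_change(rec: DegradationRecord) -> WeightChange:
    """Both weight percentages of one record; flags apparent mass gain."""
    loss = (rec.Wi - rec.Wf) / rec.Wi * 100.0
    remaining = rec.Wf / rec.Wi * 100.0
    return WeightChange(
        loss_percent=float(loss),
        remaining_percent=float(remaining),
        mass_gain_flagged=rec.Wf > rec.Wi,
    )


def degradation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized weight percentages for a (sample_id, day, Wi_mg, Wf_mg) frame."""
    out = df.copy()
    wi = out["Wi_mg"].to_numpy(float)
    wf = out["Wf_mg"].to_numpy(float)
    if np.any(wi <= 0):
        raise ValueError("all Wi_mg must be > 0")
    out["loss_percent"] = (wi - wf) / wi * 100.0
    out["remaining_percent"] = wf / wi * 100.0
    out["mass_gain_flagged"] = wf > wi
    return out


@dataclass(frozen=True)
class RelaxationResult:
    """Half-stress relaxation readout of one stress-time record."""

    sigma0: float
    tau_star: float | None  # seconds; None when right-censored
    censored: bool
    censored_at: float | None
    n_crossings: int  # downward half-level crossings seen (noise multiplicity)
    initial: str  # 'first' or 'max'
    crossing_method: str = "linear-interpolation"


def relaxation_timescale(
    times,
    stress,
    initial: str = "first",
    smooth_window: int | None = None,
) -> RelaxationResult:
    """tau*: first time the stress reaches half its initial value.

    ``initial='first'`` (default) takes sigma0 from the first sample;
    ``'max'`` from the record maximum. ``smooth_window`` applies an
    optional moving median (odd window) before crossing detection, for
    noisy rheometer traces; detection itself is plain linear interpolation
    between the bracketing samples. With noise the level may be crossed
    several times; the first crossing is used and the multiplicity
    reported.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(stress, dtype=float)
    if t.size < 2 or t.size != s.size:
        raise ValueError("need >= 2 (time, stress) samples of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
        raise ValueError("times and stress must be finite")
    if smooth_window is not None:
        if smooth_window < 3 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")
        from scipy.ndimage import median_filter

        s = median_filter(s, size=smooth_window, mode="nearest")

    if initial == "first":
        sigma0 = float(s[0])
    elif initial == "max":
        sigma0 = float(s.max())
    else:
        raise ValueError(f"unknown initial convention {initial!r}")
    half = sigma0 / 2.0

    above = s > half
    crossings = np.flatnonzero(above[:-1] & ~above[1:])
    if initial == "max":
        start = int(np.argmax(s))
        crossings = crossings[crossings >= start]
    if crossings.size == 0:
        return RelaxationResult(
            sigma0=sigma0,
            tau_star=None,
            censored=True,
            censored_at=float(t[-1]),
            n_crossings=0,
            initial=initial,
        )
    i = int(crossings[0])
    # linear interpolation between the bracketing samples
    tau_star = t[i] + (t[i + 1] - t[i]) * (s[i] - half) / (s[i] - s[i + 1])
    return RelaxationResult(
        sigma0=sigma0,
        tau_star=float(tau_star),
        censored=False,
        censored_at=None,
        n_crossings=int(crossings.size),
        initial=initial,
    )


def relative_tau_change(tau_treatment: float, tau_control: float) -> float:
    """Percent reduction of tau* relative to control.

    100 * (tau_control - tau_treatment) / tau_control: positive when the
    treated gel relaxes faster than the control, negative when slower.
    """
    if tau_control <= 0:
        raise ValueError("tau_control must be > 0")
    return 100.0 * (tau_control - tau_treatment) / tau_control
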