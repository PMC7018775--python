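"""Group statistics and reproducible end-to-end study runs.

A *study* mirrors the structure of a hydrogel formulation experiment:
named groups (e.g. Control, CNT250, CNT500, CNT750 — a filler
concentration series), each with per-assay simulation parameters, a
single global seed, and pairwise two-tailed t-tests of every group
against the control. :func:`run_study` executes the requested assays from
a config mapping and emits a deterministic, machine-readable report: the
same config + seed always produces byte-identical JSON.

Group comparison uses the classical equal-variance two-sample Student's
t-test by default (Welch available by flag), two-tailed, significance at
alpha = 0.05, no multiple-testing correction by default (optional Holm
adjustment helper provided).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as _stats

import gelcontact
from gelcontact import morphometrics, segmentation, synthetic_data
from gelcontact.cytometry import (
    CountingSpec,
    EllipseGate,
    PolygonGate,
    count_migrated,
)
from gelcontact.kinematics import DropletGeometry, cohort_summary, tracks_from_dataframe
from gelcontact.material import degradation_table, relaxation_timescale, relative_tau_change
from gelcontact.synthetic_data import (
    DegradationSimSpec,
    EllipseCell,
    EventSimSpec,
    RelaxSimSpec,
    SyntheticImageSpec,
    TrackSimSpec,
)

__all__ = [
    "GroupComparison",
    "two_tailed_t_test",
    "holm_adjust",
    "run_study",
    "geometry_gates",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-tailed two-sample t-test."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool
    equal_var: bool = True
    note: str = ""


def two_tailed_t_test(
    values_a,
    values_b,
    equal_var: bool = True,
    group_a: str = "A",
    group_b: str = "B",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-sample Student's t-test (two-tailed); Welch with equal_var=False.

    Degenerate case: both groups constant. Equal means then carry no
    evidence either way — p = 1 by convention, noted in the result; with
    different constant means the separation is total (p = 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    note = ""
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
            note = "both groups constant with equal means; p = 1 by convention"
        else:
            t, p = float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
            note = "both groups constant with different means"
    else:
        t, p = _stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=t,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        significant=p < alpha,
        equal_var=equal_var,
        note=note,
    )


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return [float(x) for x in adj]


# ---------------------------------------------------------------------------
# study execution


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def geometry_gates(spec: EventSimSpec, n_sigma: float = 6.0) -> dict:
    """Gates drawn from the known population geometry of a simulation spec.

    The cell gate is a polygon (rectangle at n_sigma marginal sds around
    the cell mean), the bead gate an ellipse — the two gate shapes used
    when discriminating fibroblasts and counting beads in SSC-A/FSC-A.
    """
    cm = np.asarray(spec.cell_mean)
    cs = np.sqrt(np.diag(np.asarray(spec.cell_cov)))
    lo = np.maximum(cm - n_sigma * cs, 0.0)
    hi = cm + n_sigma * cs
    cell_gate = PolygonGate(
        name="cells",
        channels=("FSC_A", "SSC_A"),
        vertices=((lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])),
    )
    bm = np.asarray(spec.bead_mean)
    bs = np.sqrt(np.diag(np.asarray(spec.bead_cov)))
    bead_gate = EllipseGate(
        name="beads",
        channels=("FSC_A", "SSC_A"),
        center=(float(bm[0]), float(bm[1])),
        semi_axes=(float(n_sigma * bs[0]), float(n_sigma * bs[1])),
    )
    return {"cells": cell_gate, "beads": bead_gate}


def _adhesion_assay(params: dict, seed: int) -> dict:
    """Render -> segment -> per-object ER. Cells are laid out on a jittered
    grid so the non-overlap precondition holds by construction."""
    n_images = int(params.get("n_images", 2))
    n_cells = int(params.get("n_cells", 12))
    elongation = float(params.get("elongation", 1.5))
    b_px = float(params.get("b_px", 8.0))
    ss = np.random.SeedSequence(seed)
    per_object, per_image_mean = [], []
    for img_ss in ss.spawn(n_images):
        rng = np.random.default_rng(img_ss)
        a_px = b_px * elongation
        pitch = int(np.ceil(4 * a_px))
        side = int(np.ceil(np.sqrt(n_cells)))
        size = max(64, side * pitch + pitch)
        cells = []
        for k in range(n_cells):
            gx = (k % side + 0.5) * pitch + rng.uniform(-0.1, 0.1) * pitch
            gy = (k // side + 0.5) * pitch + rng.uniform(-0.1, 0.1) * pitch
            cells.append(
                EllipseCell(
                    center=(gx + pitch / 2, gy + pitch / 2),
                    a=a_px * rng.uniform(0.9, 1.1),
                    b=b_px * rng.uniform(0.9, 1.1),
                    orientation=rng.uniform(0, np.pi),
                )
            )
        spec = SyntheticImageSpec(
            width=size + pitch, height=size + pitch, cells=tuple(cells), seed=_child_seed(img_ss)
        )
        rendered = synthetic_data.render_image(spec)
        labeled, _ = segmentation.segment(
            segmentation.RawImage(rendered.image),
            segmentation.SegmentationParams(min_area=int(params.get("min_area", 100))),
        )
        result = morphometrics.aggregate_er(morphometrics.measure_all(labeled))
        per_object.extend(result.per_object_er)
        per_image_mean.append(result.mean_er)
    return {
        "summary": {
            "mean_er_pooled": float(np.mean(per_object)),
            "mean_er_per_image": [float(x) for x in per_image_mean],
            "n_objects": len(per_object),
        },
        "values": per_object,
    }


def _recruitment_assay(params: dict, seed: int, t_eval: float) -> dict:
    spec = TrackSimSpec(
        n_cells=int(params.get("n_cells", 100)),
        n_frames=int(params.get("n_frames", int(t_eval))),
        dt=float(params.get("dt", 1.0)),
        step_sd=float(params.get("step_sd", 5.0)),
        drift_speed=float(params.get("drift_speed", 0.0)),
        seed=seed,
    )
    tracks = tracks_from_dataframe(synthetic_data.simulate_tracks(spec))
    res = cohort_summary(tracks, DropletGeometry(center=spec.center), t_eval=t_eval)
    return {
        "summary": {
            "mean_displacement_um": res.mean_displacement,
            "mean_velocity_um_per_h": res.mean_velocity,
            "sem_velocity": res.sem_velocity,
            "n_cells": res.n_cells,
        },
        "values": list(res.per_cell_velocity),
    }


def _migration_assay(params: dict, seed: int) -> dict:
    """Event-capped acquisition of a bead-spiked tube, then counting.

    The tube holds the planted migrated cells, the spiked beads and some
    debris; acquisition records ``event_cap`` events drawn in proportion
    to tube abundances, so the planted cell:bead ratio is preserved in
    expectation and recovered by the bead-referenced estimator.
    """
    counting = CountingSpec(
        encapsulated_cells=float(params.get("encapsulated_cells", 1.2e6))
    )
    migrated = float(params.get("migrated_cells", 50_000))
    debris = float(params.get("debris_in_tube", 20_000))
    event_cap = int(params.get("event_cap", 10_000))
    n_replicates = int(params.get("n_replicates", 3))
    doublet_fraction = float(params.get("doublet_fraction", 0.05))

    ss = np.random.SeedSequence(seed)
    indices, estimates = [], []
    for rep_ss in ss.spawn(n_replicates):
        rng = np.random.default_rng(rep_ss)
        abundance = np.array([migrated, counting.total_beads, debris])
        n_rec = rng.multinomial(event_cap, abundance / abundance.sum())
        spec = EventSimSpec(
            n_cells=int(n_rec[0]),
            n_beads=int(n_rec[1]),
            n_debris=int(n_rec[2]),
            doublet_fraction=doublet_fraction,
            seed=_child_seed(rep_ss),
        )
        events = synthetic_data.simulate_events(spec)
        gates = geometry_gates(spec)
        res = count_migrated(events, gates["cells"], gates["beads"], counting)
        indices.append(res.migration_index)
        estimates.append(res.estimated_cells)
    return {
        "summary": {
            "mean_migration_index": float(np.mean(indices)),
            "mean_estimated_cells": float(np.mean(estimates)),
            "planted_index": migrated / counting.encapsulated_cells,
            "n_replicates": n_replicates,
        },
        "values": indices,
    }


def _degradation_assay(params: dict, seed: int) -> dict:
    spec = DegradationSimSpec(
        Wi=float(params.get("Wi", 10.0)),
        fast_rate=float(params.get("fast_rate", 0.05)),
        slow_rate=float(params.get("slow_rate", 0.005)),
        breakpoint_day=float(params.get("breakpoint_day", 7.0)),
        noise_sd=float(params.get("noise_sd", 0.2)),
        n_replicates=int(params.get("n_replicates", 3)),
        seed=seed,
    )
    table = degradation_table(synthetic_data.simulate_degradation(spec))
    by_day = table.groupby("day")["remaining_percent"].mean()
    final_day = table["day"].max()
    values = table.loc[table["day"] == final_day, "remaining_percent"].tolist()
    return {
        "summary": {
            "remaining_percent_by_day": {f"{d:g}": float(v) for d, v in by_day.items()},
            "final_day": float(final_day),
        },
        "values": values,
    }


def _relaxation_assay(params: dict, seed: int) -> dict:
    tau = float(params.get("tau", 1000.0))
    n_replicates = int(params.get("n_replicates", 3))
    noise_sd = float(params.get("noise_sd", 0.5))
    ss = np.random.SeedSequence(seed)
    taus = []
    for rep_ss in ss.spawn(n_replicates):
        spec = RelaxSimSpec(
            sigma0=float(params.get("sigma0", 100.0)),
            tau=tau,
            noise_sd=noise_sd,
            seed=_child_seed(rep_ss),
        )
        curve = synthetic_data.simulate_relaxation(spec)
        res = relaxation_timescale(curve["t_s"], curve["sigma"])
        if res.tau_star is not None:
            taus.append(res.tau_star)
    return {
        "summary": {"mean_tau_star_s": float(np.mean(taus)), "n_replicates": len(taus)},
        "values": taus,
    }


_ASSAYS = ("adhesion", "recruitment", "migration", "degradation", "relaxation")


def run_study(config: dict, seed: int | None = None) -> dict:
    """Execute the configured assays for every group and compare to control.

    ``config`` maps: ``groups`` (list of {name, <assay>: params}),
    ``control`` (group name), ``assays`` (subset of adhesion, recruitment,
    migration, degradation, relaxation), ``t_eval`` (hours, recruitment).
    ``seed`` overrides ``config['seed']``. Returns the report dict; dump
    it with sort_keys for byte-identical reproducibility.
    """
    groups = config.get("groups") or []
    if not groups:
        raise ValueError("config must define a non-empty 'groups' list")
    names = [g["name"] for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("group labels must be unique")
    control = config.get("control", names[0])
    if control not in names:
        raise ValueError(f"control group {control!r} not among groups")
    assays = config.get("assays", list(_ASSAYS))
    unknown = set(assays) - set(_ASSAYS)
    if unknown:
        raise ValueError(f"unknown assays: {sorted(unknown)}")
    t_eval = float(config.get("t_eval", 14.0))
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    ss = np.random.SeedSequence(seed)
    group_streams = dict(zip(names, ss.spawn(len(names))))

    results: dict[str, dict] = {name: {} for name in names}
    values: dict[str, dict[str, list]] = {name: {} for name in names}
    for name, group in zip(names, groups):
        assay_streams = dict(zip(_ASSAYS, group_streams[name].spawn(len(_ASSAYS))))
        for assay in assays:
            if assay not in group:
                continue
            child = _child_seed(assay_streams[assay])
            params = group[assay] or {}
            if assay == "adhesion":
                out = _adhesion_assay(params, child)
            elif assay == "recruitment":
                out = _recruitment_assay(params, child, t_eval)
            elif assay == "migration":
                out = _migration_assay(params, child)
            elif assay == "degradation":
                out = _degradation_assay(params, child)
            else:
                out = _relaxation_assay(params, child)
            results[name][assay] = out["summary"]
            values[name][assay] = out["values"]

    comparisons = []
    for name in names:
        if name == control:
            continue
        for assay in assays:
            va = values[name].get(assay)
            vb = values[control].get(assay)
            if va and vb and len(va) >= 2 and len(vb) >= 2:
                cmp = two_tailed_t_test(va, vb, group_a=name, group_b=control)
                comparisons.append({"assay": assay, **asdict(cmp)})

    if "relaxation" in assays and "relaxation" in results[control]:
        tau_c = results[control]["relaxation"]["mean_tau_star_s"]
        for name in names:
            if name != control and "relaxation" in results[name]:
                results[name]["relaxation"]["tau_reduction_vs_control_percent"] = (
                    relative_tau_change(results[name]["relaxation"]["mean_tau_star_s"], tau_c)
                )

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "provenance": {
            "package": "gelcontact",
            "version": gelcontact.__version__,
            "seed": seed,
            "config_sha256": config_hash,
            "control": control,
            "assays": list(assays),
            "t_eval_hours": t_eval,
        },
        "groups": results,
        "comparisons": comparisons,
    }


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, stable floats)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
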