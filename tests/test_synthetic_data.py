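"""Ground-truth and determinism checks for every synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from gelcontact import synthetic_data as sd
from helpers import ellipse_perimeter_quadrature


class TestRenderImage:
    def test_zero_cells_gives_blank_noisy_image(self):
        spec = sd.SyntheticImageSpec(width=64, height=64, cells=(), noise_sd=2.0, seed=3)
        out = sd.render_image(spec)
        assert out.truth == ()
        assert not out.truth_labels.any()
        assert out.image.shape == (64, 64)
        assert abs(out.image.mean() - spec.background_intensity) < 1.0

    def test_disk_truth_uses_circle_formulas(self):
        cell = sd.EllipseCell(center=(60, 60), a=20, b=20)
        out = sd.render_image(sd.SyntheticImageSpec(width=128, height=128, cells=(cell,), seed=0))
        (truth,) = out.truth
        assert truth["minor_axis"] == truth["major_axis"] == 40.0
        assert truth["area"] == pytest.approx(400 * np.pi)
        assert truth["perimeter"] == pytest.approx(40 * np.pi)

    def test_ellipse_truth_perimeter_matches_quadrature_oracle(self):
        cell = sd.EllipseCell(center=(80, 60), a=40, b=20)
        out = sd.render_image(sd.SyntheticImageSpec(width=192, height=128, cells=(cell,), seed=0))
        p = out.truth[0]["perimeter"]
        assert p == pytest.approx(193.77, abs=0.01)
        assert p == pytest.approx(ellipse_perimeter_quadrature(40, 20), rel=1e-9)

    def test_overlapping_cells_rejected_with_diagnostic(self):
        cells = (
            sd.EllipseCell(center=(50, 50), a=20, b=10),
            sd.EllipseCell(center=(60, 50), a=20, b=10),
        )
        with pytest.raises(ValueError, match="overlap"):
            sd.render_image(sd.SyntheticImageSpec(width=128, height=128, cells=cells))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sd.EllipseCell(center=(10, 10), a=5, b=8)  # b > a
        with pytest.raises(ValueError):
            sd.SyntheticImageSpec(width=16, height=64)
        with pytest.raises(ValueError, match="outside"):
            sd.SyntheticImageSpec(
                width=64, height=64, cells=(sd.EllipseCell(center=(100, 10), a=5, b=5),)
            )

    def test_rendered_pixels_carry_cell_intensity_and_clip_at_zero(self):
        cell = sd.EllipseCell(center=(32, 32), a=10, b=10, intensity=200.0)
        out = sd.render_image(
            sd.SyntheticImageSpec(
                width=64, height=64, cells=(cell,), background_intensity=1.0, noise_sd=30.0, seed=5
            )
        )
        inside = out.truth_labels == 1
        assert out.image[inside].mean() == pytest.approx(200.0, abs=5.0)
        assert out.image.min() >= 0.0


class TestSimulateTracks:
    def test_zero_motion_cells_are_stationary(self):
        spec = sd.TrackSimSpec(n_cells=4, n_frames=5, step_sd=0.0, drift_speed=0.0, seed=1)
        df = sd.simulate_tracks(spec)
        for _, g in df.groupby("cell_id"):
            assert g["x_um"].nunique() == 1 and g["y_um"].nunique() == 1

    def test_pure_drift_closes_distance_by_speed_times_time(self):
        spec = sd.TrackSimSpec(
            n_cells=6, n_frames=14, dt=1.0, step_sd=0.0, drift_speed=5.0, seed=2
        )
        df = sd.simulate_tracks(spec)
        for _, g in df.groupby("cell_id"):
            g = g.sort_values("t_hours")
            r = np.hypot(g["x_um"], g["y_um"]).to_numpy()
            assert r[0] - r[-1] == pytest.approx(70.0, abs=1e-9)

    def test_drift_capped_at_center(self):
        spec = sd.TrackSimSpec(
            n_cells=3,
            n_frames=5,
            dt=1.0,
            step_sd=0.0,
            drift_speed=500.0,
            initial_radius_range=(100.0, 200.0),
            seed=3,
        )
        df = sd.simulate_tracks(spec)
        final = df[df["t_hours"] == df["t_hours"].max()]
        assert np.hypot(final["x_um"], final["y_um"]).max() < 1e-9

    def test_driftfree_walk_has_zero_mean_directional_displacement(self):
        """Unbiased random-walk null, verified directly from positions."""
        spec = sd.TrackSimSpec(n_cells=500, n_frames=14, step_sd=2.0, drift_speed=0.0, seed=4)
        df = sd.simulate_tracks(spec)
        d_final = []
        for _, g in df.groupby("cell_id"):
            g = g.sort_values("t_hours")
            r = np.hypot(g["x_um"], g["y_um"]).to_numpy()
            d_final.append(r[0] - r[-1])
        d_final = np.asarray(d_final)
        sem = d_final.std(ddof=1) / np.sqrt(d_final.size)
        assert abs(d_final.mean()) < 3.0 * sem

    def test_track_shape_and_time_grid(self):
        spec = sd.TrackSimSpec(n_cells=2, n_frames=3, dt=0.5, seed=0)
        df = sd.simulate_tracks(spec)
        assert len(df) == 2 * 4  # n_frames motion intervals -> n_frames+1 samples
        assert sorted(df["t_hours"].unique()) == [0.0, 0.5, 1.0, 1.5]


class TestSimulateEvents:
    def test_separable_mixture_counts_are_exact(self):
        spec = sd.EventSimSpec(n_cells=300, n_beads=200, n_debris=100, seed=5)
        ev = sd.simulate_events(spec)
        assert ev["true_label"].value_counts().to_dict() == {
            "cell": 300,
            "bead": 200,
            "debris": 100,
        }
        assert (ev[["FSC_A", "SSC_A", "FSC_H"]] >= 0).all().all()

    def test_bead_to_cell_ratio_matches_planted_ratio(self):
        spec = sd.EventSimSpec(n_cells=10_000, n_beads=5_000, n_debris=0, seed=6)
        ev = sd.simulate_events(spec)
        n_beads = (ev["true_label"] == "bead").sum()
        n_cells = (ev["true_label"] == "cell").sum()
        assert n_beads / n_cells == pytest.approx(0.5, rel=1e-9)
        # beads sit at high SSC-A / low FSC-A relative to cells
        assert ev.groupby("true_label")["SSC_A"].mean()["bead"] > ev.groupby("true_label")[
            "SSC_A"
        ].mean()["cell"]

    def test_doublets_double_area_but_not_height(self):
        spec = sd.EventSimSpec(n_cells=2000, n_beads=0, n_debris=0, doublet_fraction=0.1, seed=7)
        ev = sd.simulate_events(spec)
        doublets = ev[ev["is_doublet"]]
        assert len(doublets) == 200
        ratio = doublets["FSC_H"] / doublets["FSC_A"]
        assert ratio.median() == pytest.approx(0.5, abs=0.05)
        singl = ev[~ev["is_doublet"]]
        assert (singl["FSC_H"] / singl["FSC_A"]).median() == pytest.approx(1.0, abs=0.05)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            sd.EventSimSpec(cell_cov=((1.0, 2.0), (2.0, 1.0)))
        with pytest.raises(ValueError, match="doublet_fraction"):
            sd.EventSimSpec(doublet_fraction=1.0)


class TestSimulateRelaxation:
    def test_noiseless_closed_forms(self):
        spec = sd.RelaxSimSpec(sigma0=100.0, tau=1000.0, times=(0.0, 1000.0, 2000.0), noise_sd=0.0)
        curve = sd.simulate_relaxation(spec)
        assert curve["sigma"].iloc[0] == pytest.approx(100.0)
        assert curve["sigma"].iloc[1] == pytest.approx(100.0 / np.e)

    def test_halving_time_is_tau_log_two(self):
        spec = sd.RelaxSimSpec(
            sigma0=100.0, tau=1000.0, times=tuple(np.arange(0.0, 3000.0, 1.0)), noise_sd=0.0
        )
        curve = sd.simulate_relaxation(spec)
        below = curve[curve["sigma"] <= 50.0]
        assert below["t_s"].iloc[0] == pytest.approx(1000.0 * np.log(2), abs=1.0)

    def test_times_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            sd.RelaxSimSpec(times=(1.0, 2.0))
        with pytest.raises(ValueError):
            sd.RelaxSimSpec(times=(0.0, 2.0, 2.0))


class TestSimulateDegradation:
    def test_day_zero_and_zero_rates_preserve_initial_weight(self):
        spec = sd.DegradationSimSpec(Wi=10.0, fast_rate=0.0, slow_rate=0.0, noise_sd=0.0)
        df = sd.simulate_degradation(spec)
        assert (df["Wf_mg"] == 10.0).all()
        spec2 = sd.DegradationSimSpec(Wi=10.0, noise_sd=0.0)
        df2 = sd.simulate_degradation(spec2)
        assert (df2.loc[df2["day"] == 0.0, "Wf_mg"] == 10.0).all()

    def test_rate_inverted_from_target_remaining_weight(self):
        # choose fast_rate so W_f(7) = 7 mg, i.e. 70% remaining at day 7
        fast = -np.log(0.7) / 7.0
        spec = sd.DegradationSimSpec(Wi=10.0, fast_rate=fast, slow_rate=0.01, noise_sd=0.0)
        df = sd.simulate_degradation(spec)
        day7 = df.loc[df["day"] == 7.0, "Wf_mg"]
        assert (day7 / 10.0 * 100).to_numpy() == pytest.approx(70.0)

    def test_weights_floored_at_zero(self):
        spec = sd.DegradationSimSpec(Wi=0.5, fast_rate=1.0, noise_sd=0.4, seed=9)
        assert (sd.simulate_degradation(spec)["Wf_mg"] >= 0).all()


@pytest.mark.parametrize(
    "make",
    [
        lambda seed: sd.render_image(
            sd.SyntheticImageSpec(
                width=64,
                height=64,
                cells=(sd.EllipseCell(center=(32, 32), a=10, b=6),),
                noise_sd=3.0,
                seed=seed,
            )
        ).image,
        lambda seed: sd.simulate_tracks(sd.TrackSimSpec(n_cells=10, n_frames=5, seed=seed)),
        lambda seed: sd.simulate_events(
            sd.EventSimSpec(n_cells=200, n_beads=100, n_debris=50, doublet_fraction=0.1, seed=seed)
        ),
        lambda seed: sd.simulate_relaxation(
            sd.RelaxSimSpec(times=tuple(np.arange(0.0, 100.0, 1.0)), noise_sd=1.0, seed=seed)
        ),
        lambda seed: sd.simulate_degradation(sd.DegradationSimSpec(noise_sd=0.2, seed=seed)),
    ],
    ids=["image", "tracks", "events", "relaxation", "degradation"],
)
def test_generators_are_bit_identical_under_same_seed(make):
    a, b, c = make(42), make(42), make(43)
    if isinstance(a, pd.DataFrame):
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)
    else:
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
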