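"""Step velocities, turning angles, summaries, smoothing, drift QC."""

import numpy as np
import pandas as pd
import pytest

from algastress.motility import (
    angle_histogram,
    angles_table,
    directional_changes,
    heading_uniformity,
    histogram,
    modal_bin_center,
    percent_change,
    smooth_track,
    speed_histogram,
    step_velocities,
    steps_table,
    summarize_condition,
)
from algastress.synthetic import SwimmerParams, simulate_swimmers
from conftest import DT, gt_tracks


def make_track(points, frames=None, track_id=0):
    points = np.asarray(points, dtype=float)
    frames = np.arange(len(points)) if frames is None else np.asarray(frames)
    return pd.DataFrame(
        {"track_id": track_id, "frame": frames,
         "x_um": points[:, 0], "y_um": points[:, 1]}
    )


class TestStepVelocities:
    def test_unit_steps_give_inverse_dt_speed(self):
        tr = make_track([(0, 0), (1, 0), (2, 0)])
        st = step_velocities(tr, DT)
        assert len(st) == 2
        assert np.allclose(st["speed"], 1.0 / DT)  # 25.2525... um/s

    def test_static_track_zero_speed(self):
        tr = make_track([(3, 4)] * 5)
        assert (step_velocities(tr, DT)["speed"] == 0).all()

    def test_gap_rule(self):
        tr = make_track([(0, 0), (1, 0), (5, 0), (6, 0)], frames=[0, 1, 5, 6])
        st = step_velocities(tr, DT)
        assert len(st) == 2  # only 0->1 and 5->6

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            step_velocities(make_track([(0, 0), (1, 0)]), 0.0)


class TestDirectionalChanges:
    def test_right_angle_turn_ccw(self):
        # steps (1,0) then (0,1): quarter turn, positive cross product
        tr = make_track([(0, 0), (1, 0), (1, 1)])
        an = directional_changes(tr, DT)
        assert an["dtheta"].iloc[0] == pytest.approx(np.pi / 2)
        assert an["dtheta_signed"].iloc[0] == pytest.approx(np.pi / 2)

    def test_right_angle_turn_cw_negative(self):
        tr = make_track([(0, 0), (1, 0), (1, -1)])
        an = directional_changes(tr, DT)
        assert an["dtheta_signed"].iloc[0] == pytest.approx(-np.pi / 2)

    def test_straight_motion_zero(self):
        tr = make_track([(0, 0), (1, 0), (2, 0)])
        assert directional_changes(tr, DT)["dtheta"].iloc[0] == 0.0

    def test_reversal_is_plus_pi(self):
        tr = make_track([(0, 0), (1, 0), (0, 0)])
        an = directional_changes(tr, DT)
        assert an["dtheta"].iloc[0] == pytest.approx(np.pi)
        assert an["dtheta_signed"].iloc[0] == pytest.approx(np.pi)  # tie -> +pi

    def test_zero_length_step_dropped(self):
        tr = make_track([(0, 0), (0, 0), (1, 0), (2, 0)])
        an = directional_changes(tr, DT)
        assert len(an) == 1  # only the pair of two nonzero steps

    def test_angles_need_shared_middle_frame(self):
        tr = make_track([(0, 0), (1, 0), (2, 0), (3, 0)], frames=[0, 1, 3, 4])
        an = directional_changes(tr, DT)
        assert len(an) == 0  # steps 0->1 and 3->4 do not share a frame

    def test_clamping_never_nan(self):
        # nearly parallel steps can push the cosine past 1 by float error
        tr = make_track([(0, 0), (1e-7, 1e-9), (2e-7, 2e-9)])
        an = directional_changes(tr, DT)
        assert np.isfinite(an["dtheta"]).all()

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 1, (30, 2)), axis=0)
        tr = make_track(pts)
        phi = 0.7321
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        tr_rot = make_track(pts @ R.T)
        s0, s1 = step_velocities(tr, DT), step_velocities(tr_rot, DT)
        a0, a1 = directional_changes(tr, DT), directional_changes(tr_rot, DT)
        assert np.allclose(s0["speed"], s1["speed"], atol=1e-9)
        assert np.allclose(a0["dtheta"], a1["dtheta"], atol=1e-9)


class TestSignedAngleSymmetry:
    def test_zero_mean_and_symmetric_distribution(self):
        """Unbiased turning: mean signed angle within 3 SE of zero and the
        +/- halves of the distribution agree (KS distance < 0.1)."""
        gt = simulate_swimmers(
            SwimmerParams(n_cells=40, duration_frames=500), seed=13
        )
        an = angles_table(gt_tracks(gt), DT)
        signed = an["dtheta_signed"].to_numpy()
        se = signed.std(ddof=1) / np.sqrt(len(signed))
        assert abs(signed.mean()) < 3 * se
        pos = np.sort(signed[signed > 0])
        neg = np.sort(-signed[signed < 0])
        grid = np.linspace(0, np.pi, 200)
        cdf_p = np.searchsorted(pos, grid) / len(pos)
        cdf_n = np.searchsorted(neg, grid) / len(neg)
        assert np.abs(cdf_p - cdf_n).max() < 0.1


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            (59.0, 12.0, -79.66),   # strong dose: ~80% speed reduction
            (61.0, 22.0, -63.93),
            (61.0, 48.0, -21.31),   # control drift
            (0.81, 1.80, 122.22),   # turning-angle increase
            (0.78, 1.50, 92.31),
            (0.72, 0.89, 23.61),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_worked_examples(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.01)

    def test_zero_before_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestSummarize:
    def _steps(self, speeds, track_id=0):
        return pd.DataFrame(
            {"track_id": track_id, "t": np.arange(len(speeds)) * DT,
             "vx": speeds, "vy": 0.0, "speed": speeds}
        )

    def _angles(self, vals):
        return pd.DataFrame(
            {"track_id": 0, "t": np.arange(len(vals)) * DT,
             "dtheta": vals, "dtheta_signed": vals}
        )

    def test_identical_replicates_zero_sd(self):
        st = self._steps([10.0, 20.0])
        an = self._angles([0.5, 0.7])
        s = summarize_condition([st, st, st], [an, an, an])
        assert s.mean_speed == pytest.approx(15.0)
        assert s.sd_speed == 0.0
        assert s.mean_dtheta == pytest.approx(0.6)

    def test_hierarchy_replicate_means_then_condition(self):
        # replicate means 10 and 30 -> condition mean 20, not pooled 25
        s = summarize_condition(
            [self._steps([10.0]), self._steps([20.0, 40.0])],
            [self._angles([0.1]), self._angles([0.2])],
        )
        assert s.mean_speed == pytest.approx(20.0)

    def test_empty_replicate_excluded_with_warning(self):
        st = self._steps([10.0])
        empty = st.iloc[0:0]
        with pytest.warns(UserWarning):
            s = summarize_condition([st, empty], [self._angles([0.1]), empty])
        assert s.n_replicates == 1

    def test_no_replicates_raises(self):
        with pytest.raises(ValueError):
            summarize_condition([], [])


class TestHistogram:
    def test_fixed_bins_and_frequencies(self):
        h = histogram([1.0, 6.0, 7.0, 149.0], 5.0, (0.0, 150.0))
        assert len(h) == 30
        assert h["count"].sum() == 4
        assert h.loc[1, "count"] == 2  # [5, 10)
        assert h["frequency"].sum() == pytest.approx(1.0)

    def test_empty_series(self):
        assert len(histogram([], 5.0, (0.0, 150.0))) == 0

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            histogram([1.0], 0.0, (0.0, 1.0))


class TestSmoothTrack:
    def _noisy_line(self, n=50, noise=0.3, seed=2):
        rng = np.random.default_rng(seed)
        x = np.arange(n) * 1.5
        return make_track(
            np.c_[x + rng.normal(0, noise, n), rng.normal(0, noise, n)]
        )

    def test_zero_reg_returns_raw(self):
        tr = self._noisy_line()
        out = smooth_track(tr, 0.0)
        assert np.allclose(out["x_um"], tr["x_um"])

    def test_straight_line_unchanged(self):
        tr = make_track([(i * 2.0, 5.0) for i in range(20)])
        for reg in (0.1, 1.0, 10.0):
            out = smooth_track(tr, reg)
            assert np.allclose(out["x_um"], tr["x_um"], atol=1e-6)
            assert np.allclose(out["y_um"], tr["y_um"], atol=1e-6)

    def test_smoothing_reduces_roughness(self):
        tr = self._noisy_line()
        rough_raw = np.abs(np.diff(tr["y_um"], 2)).mean()
        rough_s = np.abs(np.diff(smooth_track(tr, 10.0)["y_um"], 2)).mean()
        assert rough_s < rough_raw

    def test_trend_robust_to_regularization(self):
        """Treated < control speed and treated > control turning, for raw
        and smoothed tracks at every regularization weight."""
        control = simulate_swimmers(
            SwimmerParams(n_cells=20, duration_frames=150), seed=14
        )
        treated = simulate_swimmers(
            SwimmerParams(n_cells=20, duration_frames=150, ag_conc=2.35,
                          exposure_min=60.0),
            seed=15,
        )
        for reg in (0.0, 0.1, 1.0, 10.0):
            stats = {}
            for name, gt in (("control", control), ("treated", treated)):
                tracks = gt_tracks(gt)
                smoothed = pd.concat(
                    [smooth_track(tr, reg) for _, tr in tracks.groupby("track_id")],
                    ignore_index=True,
                )
                stats[name] = (
                    steps_table(smoothed, DT)["speed"].mean(),
                    angles_table(smoothed, DT)["dtheta"].mean(),
                )
            assert stats["treated"][0] < stats["control"][0]
            assert stats["treated"][1] > stats["control"][1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            smooth_track(make_track([(0, 0)] * 10), -1.0)
        with pytest.raises(ValueError):
            smooth_track(make_track([(0, 0), (1, 1), (2, 2)]), 1.0)


class TestHeadingUniformity:
    def test_uniform_grid_R_near_zero(self):
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        steps = pd.DataFrame(
            {"vx": np.cos(theta), "vy": np.sin(theta), "speed": 1.0,
             "track_id": 0, "t": 0.0}
        )
        R, p = heading_uniformity(steps)
        assert R < 1e-10
        assert p > 0.99

    def test_common_heading_R_one(self):
        steps = pd.DataFrame(
            {"vx": np.ones(50), "vy": np.zeros(50), "speed": 1.0,
             "track_id": 0, "t": 0.0}
        )
        R, p = heading_uniformity(steps)
        assert R == pytest.approx(1.0)
        assert p < 1e-6

    def test_drift_detected(self):
        """Adding a 10 um/s drift to a control fixture trips the QC gate."""
        gt = simulate_swimmers(
            SwimmerParams(n_cells=40, duration_frames=300), seed=16
        )
        steps = steps_table(gt_tracks(gt), DT)
        R0, _ = heading_uniformity(steps)
        assert R0 < 0.2  # headings roughly homogeneous without drift
        drifted = steps.copy()
        drifted["vx"] += 10.0
        R1, p1 = heading_uniformity(drifted)
        assert R1 > R0
        assert p1 < 0.01

    def test_matches_reference_implementation(self):
        """Cross-check R and p against pingouin's Rayleigh test."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        theta = rng.vonmises(0.0, 0.5, size=200)
        steps = pd.DataFrame(
            {"vx": np.cos(theta), "vy": np.sin(theta), "speed": 1.0,
             "track_id": 0, "t": 0.0}
        )
        R, p = heading_uniformity(steps)
        z_ref, p_ref = pingouin.circ_rayleigh(theta)
        assert p == pytest.approx(p_ref, rel=1e-3, abs=1e-6)

    def test_too_few_steps(self):
        steps = pd.DataFrame({"vx": [1.0], "vy": [0.0]})
        with pytest.raises(ValueError):
            heading_uniformity(steps)


class TestDistributionShapes:
    def test_control_speed_mode_through_pipeline(self, control_pipeline_tracks):
        """Full pipeline recovers the generator's 45 um/s speed mode."""
        steps = steps_table(control_pipeline_tracks, DT)
        mode = modal_bin_center(speed_histogram(steps))
        assert abs(mode - 45.0) <= 5.0

    def test_stalled_speed_mode_at_zero(self, stalled_pipeline_tracks):
        steps = steps_table(stalled_pipeline_tracks, DT)
        h = speed_histogram(steps)
        assert h["count"].idxmax() == 0  # modal bin is the 0-bin

    def test_stalled_angles_bimodal_at_zero_and_pi(self, stalled_pipeline_tracks):
        angles = angles_table(stalled_pipeline_tracks, DT)
        h = angle_histogram(angles)
        counts = h["count"].to_numpy()
        interior = counts[3:-3]
        assert counts[0] > 2 * interior.min()
        assert counts[-1] > 2 * interior.min()
        # both end peaks dominate the central region
        assert counts[0] > np.median(interior)
        assert counts[-1] > np.median(interior)
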