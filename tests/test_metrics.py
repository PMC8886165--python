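"""Circle fitting, rotation angle and per-phase metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import acromotion as am
from acromotion.exceptions import DegenerateGeometryError, ZeroArcError
from acromotion.metrics import CircleFitResult
from acromotion.phases import PhaseSegment


def grid_min_cost(pts, center, radius, half=0.5, step=0.01):
    """Brute-force minimum of the geometric cost over a dense grid around
    (center, radius): the independent oracle for fit optimality."""
    xs = center[0] + np.arange(-half, half + step / 2, step)
    ys = center[1] + np.arange(-half, half + step / 2, step)
    rs = radius + np.arange(-half, half + step / 2, step)
    dx = pts[:, 0][None, None, :] - xs[:, None, None]
    dy = pts[:, 1][None, None, :] - ys[None, :, None]
    d = np.sqrt(dx**2 + dy**2)  # (nx, ny, npts)
    s1 = d.sum(axis=2)
    s2 = (d**2).sum(axis=2)
    n = pts.shape[0]
    # cost(r) = sum d^2 - 2 r sum d + n r^2, minimised over the r grid
    costs = s2[..., None] - 2 * rs[None, None, :] * s1[..., None] + n * rs[None, None, :] ** 2
    return float(costs.min())


class TestFitCircle:
    def test_exact_unit_circle(self):
        pts = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)], dtype=float)
        fit = am.fit_circle(pts)
        assert fit.xc == pytest.approx(0, abs=1e-12)
        assert fit.yc == pytest.approx(0, abs=1e-12)
        assert fit.rc == pytest.approx(1, abs=1e-12)
        assert fit.cost < 1e-12
        assert fit.converged

    def test_circumcircle_of_three_points(self):
        fit = am.fit_circle(np.array([(0, 0), (2, 0), (1, 1)], dtype=float))
        assert (fit.xc, fit.yc) == (pytest.approx(1, abs=1e-9), pytest.approx(0, abs=1e-9))
        assert fit.rc == pytest.approx(1, abs=1e-9)
        assert fit.cost < 1e-12

    def test_noisy_circle_recovery_and_grid_optimality(self, make_circle_points):
        """Recovered parameters land within 0.05 of truth and the returned
        cost beats every candidate on a dense brute-force grid."""
        rng = np.random.default_rng(1)
        center, radius = (3.0, -2.0), 4.86
        pts = make_circle_points(center, radius, np.linspace(0, 360, 20, endpoint=False))
        pts += rng.normal(0, 0.05, pts.shape)
        fit = am.fit_circle(pts)
        assert fit.xc == pytest.approx(center[0], abs=0.05)
        assert fit.yc == pytest.approx(center[1], abs=0.05)
        assert fit.rc == pytest.approx(radius, abs=0.05)
        assert fit.cost <= grid_min_cost(pts, center, radius) + 1e-12

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([(0, 0), (1, 1), (2, 2), (3, 3)], dtype=float),  # collinear
            np.array([(1, 1), (1, 1), (1, 1)], dtype=float),  # coincident
            np.array([(0, 0), (1, 0)], dtype=float),  # too few
        ],
        ids=["collinear", "coincident", "too-few"],
    )
    def test_degenerate_geometry_rejected(self, pts):
        with pytest.raises((DegenerateGeometryError, ValueError)):
            am.fit_circle(pts)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
        rot=st.floats(0, 360),
    )
    def test_equivariance_under_rigid_motion(self, dx, dy, rot):
        """Translation moves the centre identically; rotation about any pivot
        leaves radius and cost unchanged."""
        rng = np.random.default_rng(7)
        a = np.linspace(0.3, 2.2, 12)
        pts = np.column_stack([4 * np.cos(a) + 1, 4 * np.sin(a) - 2])
        pts += rng.normal(0, 0.03, pts.shape)
        base = am.fit_circle(pts)
        shifted = am.fit_circle(pts + [dx, dy])
        assert shifted.xc == pytest.approx(base.xc + dx, abs=1e-6)
        assert shifted.yc == pytest.approx(base.yc + dy, abs=1e-6)
        assert shifted.rc == pytest.approx(base.rc, abs=1e-7)
        c, s = np.cos(np.radians(rot)), np.sin(np.radians(rot))
        R = np.array([[c, -s], [s, c]])
        rotated = am.fit_circle(pts @ R.T)
        assert rotated.rc == pytest.approx(base.rc, abs=1e-7)
        assert rotated.cost == pytest.approx(base.cost, abs=1e-9)


def _fit(center=(0.0, 0.0), rc=1.0):
    return CircleFitResult(center[0], center[1], rc, 0.0, 3, True)


class TestRotationAngle:
    @pytest.mark.parametrize(
        "left, right, expected",
        [((0.5, 0.866), (1.0, 0.0), 60.0), ((0.707, 0.707), (1.0, 0.0), 45.0)],
    )
    def test_known_angles_about_origin(self, left, right, expected):
        pts = np.array([left, right])
        res = am.rotation_angle(_fit(), pts)
        assert res.theta == pytest.approx(expected, abs=0.01)
        assert res.endpoint_left == pytest.approx(left)
        assert res.endpoint_right == pytest.approx(right)
        assert not res.exceeds_90

    def test_angle_at_least_90_flagged_not_clamped(self):
        pts = np.array([(-1.0, 0.2), (1.0, 0.2)])
        with pytest.warns(UserWarning, match="90"):
            res = am.rotation_angle(_fit(center=(0, 0.2)), pts)
        assert res.exceeds_90
        assert res.theta == pytest.approx(180.0, abs=1e-6)

    def test_leftmost_tie_goes_to_earliest_frame(self):
        pts = np.array([(0.0, 1.0), (0.0, -1.0), (1.0, 0.0)])
        res = am.rotation_angle(_fit(), pts)
        assert res.endpoint_left == (0.0, 1.0)
        assert res.theta == pytest.approx(90.0, abs=1e-9)

    def test_zero_arc_rejected(self):
        pts = np.array([(1.0, 0.0), (1.0, 0.0)])
        with pytest.raises(ZeroArcError):
            am.rotation_angle(_fit(), pts)

    def test_simulated_arc_recovered(self):
        """Noisy 36-deg sweeps come back within 2 deg (median over seeds)."""
        errs = []
        for seed in range(15):
            cfg = am.MotionConfig(true_sweep=36.0, seed=seed)
            frames, _ = am.simulate_recording(cfg)
            traj = am.to_relative_trajectory(frames, cfg.calibration)
            segs = am.trim_middle_cycles(
                am.segment_phases(traj, am.detect_extrema(traj.x))
            )
            metrics = am.compute_phase_metrics(traj, segs)
            errs.append(abs(np.mean([m.rotation.theta for m in metrics]) - 36.0))
        assert np.median(errs) < 2.0


class TestChordAngleLaw:
    def test_theta_matches_chord_formula_and_monotone(self, make_circle_points):
        """For noiseless arcs with fixed chord c, theta = 2 arcsin(c/(2 rc))
        to 1e-6, hence radius and angle are strictly inversely related
        (Spearman rho = -1 over a radius grid)."""
        chord = 3.0
        radii = np.linspace(2.5, 8.0, 12)
        thetas = []
        for r in radii:
            half = np.degrees(np.arcsin(chord / (2 * r)))
            angles = np.linspace(90 - half, 90 + half, 15)
            pts = make_circle_points((0.0, 0.0), r, angles)
            fit = am.fit_circle(pts)
            res = am.rotation_angle(fit, pts)
            expected = np.degrees(2 * np.arcsin(chord / (2 * fit.rc)))
            assert res.theta == pytest.approx(expected, abs=1e-6)
            thetas.append(res.theta)
        rho = spearmanr(radii, thetas).statistic
        assert rho == -1.0


class TestMinVerticalAHD:
    def _traj(self, y):
        y = np.asarray(y, dtype=float)
        n = y.size
        return am.RelativeTrajectory(
            times=np.arange(n) / 4.0, x=np.linspace(0, 1, n), y=y
        )

    def test_minimum_over_segment(self):
        traj = self._traj([0.5, 0.3, 0.4])
        seg = PhaseSegment("abduction", 0, 2, 1)
        assert am.min_vertical_ahd(traj, seg) == pytest.approx(0.3)

    def test_constant_segment(self):
        traj = self._traj([0.4] * 5)
        assert am.min_vertical_ahd(traj, PhaseSegment("abduction", 0, 4, 1)) == 0.4

    def test_negative_values_clipped_with_warning(self):
        traj = self._traj([0.5, -0.2, 0.4])
        with pytest.warns(UserWarning, match="clipped"):
            v = am.min_vertical_ahd(traj, PhaseSegment("abduction", 0, 2, 1))
        assert v == 0.0

    def test_non_increasing_when_a_sample_decreases(self):
        y = np.array([0.5, 0.35, 0.42, 0.6])
        seg = PhaseSegment("abduction", 0, 3, 1)
        base = am.min_vertical_ahd(self._traj(y), seg)
        for i in range(4):
            y2 = y.copy()
            y2[i] -= 0.1
            assert am.min_vertical_ahd(self._traj(y2), seg) <= base

    def test_simulated_minimum_recovered(self):
        """Programmed 0.29 cm minimum recovered within 0.03 cm at low noise."""
        cfg = am.MotionConfig(min_separation=0.29, noise_sd=0.01, seed=4)
        frames, _ = am.simulate_recording(cfg)
        traj = am.to_relative_trajectory(frames, cfg.calibration)
        segs = am.trim_middle_cycles(
            am.segment_phases(traj, am.detect_extrema(traj.x))
        )
        vals = [am.min_vertical_ahd(traj, s) for s in segs]
        assert np.mean(vals) == pytest.approx(0.29, abs=0.03)


class TestAverages:
    def test_mean_per_direction(self):
        cfg = am.MotionConfig(noise_sd=0.0, drift_amplitude=0.0)
        frames, _ = am.simulate_recording(cfg)
        traj = am.to_relative_trajectory(frames, cfg.calibration)
        segs = am.trim_middle_cycles(
            am.segment_phases(traj, am.detect_extrema(traj.x))
        )
        metrics = am.compute_phase_metrics(traj, segs)
        avg = am.average_by_direction(metrics)
        ab = [m.min_vertical_ahd for m in metrics if m.direction == "abduction"]
        assert avg["abduction"]["min_vertical_ahd"] == pytest.approx(np.mean(ab))
        assert set(avg) == {"abduction", "adduction"}

    def test_single_phase_mean_is_identity(self):
        cfg = am.MotionConfig(noise_sd=0.0, drift_amplitude=0.0)
        frames, _ = am.simulate_recording(cfg)
        traj = am.to_relative_trajectory(frames, cfg.calibration)
        segs = am.trim_middle_cycles(
            am.segment_phases(traj, am.detect_extrema(traj.x))
        )
        metrics = am.compute_phase_metrics(traj, segs[:1])
        with pytest.warns(UserWarning, match="adduction"):
            avg = am.average_by_direction(metrics)
        assert avg["abduction"]["min_vertical_ahd"] == metrics[0].min_vertical_ahd
        assert "adduction" not in avg

    def test_averaging_beats_single_cycles(self):
        """Across seeds, the per-direction mean radius is closer to truth on
        average than individual cycle estimates are."""
        err_mean, err_single = [], []
        for seed in range(40):
            cfg = am.MotionConfig(seed=seed)
            frames, truth = am.simulate_recording(cfg)
            traj = am.to_relative_trajectory(frames, cfg.calibration)
            segs = am.trim_middle_cycles(
                am.segment_phases(traj, am.detect_extrema(traj.x))
            )
            metrics = [m for m in am.compute_phase_metrics(traj, segs)
                       if m.direction == "abduction"]
            radii = np.array([m.fit.rc for m in metrics])
            err_mean.append(abs(radii.mean() - truth.true_radius))
            err_single.append(np.mean(np.abs(radii - truth.true_radius)))
        assert np.mean(err_mean) < np.mean(err_single)
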