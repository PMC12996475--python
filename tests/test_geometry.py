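import numpy as np
import pytest

from ribmpr.detection import Detection
from ribmpr.geometry import (EvalConfig, FittedPlane, RibTrajectory,
                             evaluate_plane, fit_plane_lsq, label_ribs,
                             plane_set_for_rib, tracks_to_trajectories,
                             two_fit_planes)
from ribmpr.tracking import KalmanBoxState, Track


def make_track(track_id, entries):
    t = Track(track_id=track_id, kalman=KalmanBoxState((0, 0, 4, 4)))
    for frame, cx, cy in entries:
        t.history.append((frame, Detection(frame, cx, cy, 4.0, 4.0, 0.9)))
    return t


class TestTrajectories:
    def test_index_to_mm_map(self):
        track = make_track(0, [(5, 10.0, 20.0)])
        trajs = tracks_to_trajectories([track], spacing=(1.0, 1.0, 2.0))
        np.testing.assert_allclose(trajs[0].points, [[10.0, 20.0, 10.0]])

    def test_empty_track_list(self):
        assert tracks_to_trajectories([], (1, 1, 1)) == []

    def test_class_mode_merges_same_label(self):
        a = make_track(0, [(k, 10.0, 10.0 + k) for k in range(5)])
        b = make_track(1, [(k, 30.0, 10.0 + k) for k in range(5)])
        for t in (a, b):
            for f, d in t.history:
                d.class_label = "L5"
        merged = tracks_to_trajectories([a, b], (1, 1, 1), mode="class")
        assert len(merged) == 1
        assert len(merged[0]) == 10
        assert merged[0].track_ids == (0, 1)

    def test_geometric_mode_merges_only_nearby_endpoints(self):
        a = make_track(0, [(k, 10.0, 10.0) for k in range(5)])
        b = make_track(1, [(k, 10.0, 12.0) for k in range(6, 10)])  # gap ~2mm
        c = make_track(2, [(k, 90.0, 90.0) for k in range(5)])
        out = tracks_to_trajectories([a, b, c], (1, 1, 1), mode="geometric",
                                     merge_dist_mm=8.0)
        sizes = sorted(len(t) for t in out)
        assert sizes == [5, 9]


def _gt_trajectories(gt, spacing, mirror_x=None):
    """Build unlabeled trajectory candidates straight from ground truth."""
    out = []
    for i, rid in enumerate(sorted(gt.ribs)):
        ents = sorted((e for e in gt.crossings if e.rib_id == rid),
                      key=lambda e: e.frame)
        pts = np.array([[e.center_px[0] * spacing[0],
                         e.center_px[1] * spacing[1],
                         e.frame * spacing[2]] for e in ents])
        if mirror_x is not None:
            pts[:, 0] = mirror_x - pts[:, 0]
        out.append(RibTrajectory(pts, np.array([e.frame for e in ents]), (i,)))
    return out


class TestLabeling:
    def test_phantom_trajectories_label_with_zero_order_errors(self, phantom_clean):
        volume, gt = phantom_clean
        trajs = _gt_trajectories(gt, volume.spacing)
        labeled, report = label_ribs(trajs, volume.shape, volume.spacing)
        assert report.all_labeled
        # each labeled trajectory must match the rib whose crossings built it
        for traj in labeled:
            rid = sorted(gt.ribs)[traj.track_ids[0]]
            assert traj.label == rid

    def test_missing_rib_flags_side_but_labels_other(self, phantom_clean):
        volume, gt = phantom_clean
        trajs = [t for t in _gt_trajectories(gt, volume.spacing)
                 if sorted(gt.ribs)[t.track_ids[0]] != "L7"]
        labeled, report = label_ribs(trajs, volume.shape, volume.spacing)
        assert not report.side_ok["left"]
        assert report.side_ok["right"]
        assert report.side_counts["left"] == 11

    def test_mirrored_volume_swaps_sides_exactly(self, phantom_clean):
        volume, gt = phantom_clean
        width_mm = (volume.shape[2] - 1) * volume.spacing[0]
        plain, _ = label_ribs(_gt_trajectories(gt, volume.spacing),
                              volume.shape, volume.spacing)
        mirrored, _ = label_ribs(
            _gt_trajectories(gt, volume.spacing, mirror_x=width_mm),
            volume.shape, volume.spacing)
        lab_plain = {t.track_ids[0]: t.label for t in plain}
        lab_mirr = {t.track_ids[0]: t.label for t in mirrored}
        flip = {"L": "R", "R": "L"}
        assert all(lab_mirr[k] == flip[v[0]] + v[1:] for k, v in lab_plain.items())


class TestPlaneFit:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-10, 10, (50, 2))
        pts = np.column_stack([xy, 2 * xy[:, 0] + 3 * xy[:, 1] + 1])
        plane = fit_plane_lsq(pts)
        assert plane.coef == pytest.approx((2.0, 3.0, 1.0), abs=1e-9)
        assert plane.r2 == pytest.approx(1.0)
        assert plane.r == pytest.approx(1.0)
        assert not plane.degenerate

    def test_horizontal_points_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-10, 10, (40, 2))
        pts = np.column_stack([xy, np.full(40, 5.0)])  # all z equal
        plane = fit_plane_lsq(pts)
        assert plane.degenerate
        assert np.isnan(plane.r2)

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0),
                               np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_plane_lsq(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_plane_lsq(np.zeros((2, 3)))

    def test_noisy_plane_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        n = 200
        xy = rng.uniform(-20, 20, (n, 2))
        z = 1.5 * xy[:, 0] - 0.8 * xy[:, 1] + 4.0 + rng.normal(0, 0.5, n)
        pts = np.column_stack([xy, z])
        plane = fit_plane_lsq(pts)
        # independent normal-equations solve
        X = np.column_stack([xy, np.ones(n)])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        assert plane.coef == pytest.approx(tuple(beta), abs=1e-9)
        zhat = X @ beta
        r2_oracle = 1 - np.sum((z - zhat) ** 2) / np.sum((z - z.mean()) ** 2)
        assert plane.r2 == pytest.approx(r2_oracle, abs=1e-9)
        # coefficient recovery within 3 SE
        resid = z - zhat
        sigma2 = resid @ resid / (n - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for est, true, var in zip(beta, (1.5, -0.8, 4.0), np.diag(cov)):
            assert abs(est - true) < 3 * np.sqrt(var)

    def test_r_squared_equals_r2_identity(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-5, 5, (80, 2))
        z = 0.3 * xy[:, 0] + 0.7 * xy[:, 1] + rng.normal(0, 1.0, 80)
        plane = fit_plane_lsq(np.column_stack([xy, z]))
        assert plane.r ** 2 == pytest.approx(plane.r2, abs=1e-12)


class TestEvaluation:
    def _plane(self, r, r2, degenerate=False):
        return FittedPlane((0, 0, 0), np.array([0, 0, 1.0]), r, r2,
                           degenerate, (0, 10))

    def test_accept_reject_threshold(self):
        cfg = EvalConfig()
        assert evaluate_plane(self._plane(0.997, 0.995), cfg)
        assert not evaluate_plane(self._plane(0.997, 0.98), cfg)
        assert not evaluate_plane(self._plane(0.98, 0.995), cfg)
        assert not evaluate_plane(self._plane(0.999, 0.999, degenerate=True), cfg)

    def test_monotone_in_both_metrics(self):
        cfg = EvalConfig()
        base_r, base_r2 = 0.992, 0.991
        assert evaluate_plane(self._plane(base_r, base_r2), cfg)
        for dr in (0.001, 0.005):
            assert evaluate_plane(self._plane(base_r + dr, base_r2 + dr), cfg)


def _dihedral_points(n=60, bend_frac=0.5, slope1=0.6, slope2=-0.2):
    """Exact roof: two half-planes joined along the y axis."""
    t = np.linspace(-10, 10, n)
    rng = np.random.default_rng(0)
    y = rng.uniform(-5, 5, n)
    kb = int(n * bend_frac)
    z = np.where(np.arange(n) < kb,
                 slope1 * (t - t[kb]), slope2 * (t - t[kb])) + 0.25 * y
    return np.column_stack([t, y, z]), kb


class TestTwoFit:
    def test_dihedral_recovered_with_true_bend_index(self):
        pts, kb = _dihedral_points()
        single = fit_plane_lsq(pts)
        assert single.r2 < 0.99
        ps = two_fit_planes(pts)
        assert ps.method == "two_fit"
        assert abs(ps.split_index - kb) <= 2
        for pl in ps.planes:
            assert pl.r2 == pytest.approx(1.0, abs=1e-9)
        # segments partition the index range
        (a0, a1), (b0, b1) = ps.planes[0].index_range, ps.planes[1].index_range
        assert (a0, a1, b0, b1) == (0, ps.split_index, ps.split_index, len(pts))

    def test_exact_plane_ties_break_to_smallest_split(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-10, 10, (40, 2))
        pts = np.column_stack([xy, 0.5 * xy[:, 0] + 0.2 * xy[:, 1]])
        cfg = EvalConfig()
        ps = two_fit_planes(pts, cfg)
        g = cfg.split_guard_points
        min_seg = max(cfg.min_segment_points, int(np.ceil(0.2 * len(pts))))
        assert ps.split_index == min_seg + g
        for pl in ps.planes:
            assert pl.r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_small_to_split_raises(self):
        pts, _ = _dihedral_points(n=6)
        with pytest.raises(ValueError, match="too small"):
            two_fit_planes(pts)


class TestPlaneSetForRib:
    def _traj(self, pts):
        return RibTrajectory(pts, np.arange(len(pts)), (0,), "left", 5)

    def test_planar_trajectory_selects_one_fit(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(-30, 30, (50, 2))
        pts = np.column_stack([xy, 0.4 * xy[:, 0] + 0.1 * xy[:, 1] + 2.0])
        ps = plane_set_for_rib(self._traj(pts))
        assert ps.method == "one_fit"

    def test_bent_trajectory_selects_two_fit(self):
        pts, _ = _dihedral_points()
        ps = plane_set_for_rib(self._traj(pts))
        assert ps.method == "two_fit"
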