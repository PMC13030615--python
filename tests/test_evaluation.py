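"""Metrics: segment-length variation, 2D keypoint scores, run-level stats."""

import numpy as np
import pytest
from scipy import stats

from ptzmocap import evaluation
from ptzmocap.types import (
    ConfigurationError,
    Pose3D,
    PoseObservation,
    RefDetection,
    SkeletonModel,
)


def _two_point_skeleton():
    return SkeletonModel(
        keypoint_names=("a", "b"),
        segments={"seg": ("a", "b")},
        segment_lengths={"seg": 0.3},
    )


def _poses_with_lengths(lengths):
    poses = []
    for f, L in enumerate(lengths):
        pts = np.array([[0.0, 0.0, 0.0], [L, 0.0, 0.0]])
        poses.append(Pose3D(frame=f, points=pts, n_views=np.array([2, 2])))
    return poses


class TestSegmentLengths:
    def test_hand_computed_three_frame_toy(self):
        report = evaluation.segment_lengths(
            _poses_with_lengths([0.30, 0.32, 0.34]), _two_point_skeleton()
        )
        assert report.sd["seg"] == pytest.approx(0.02)
        assert report.mean["seg"] == pytest.approx(0.32)
        assert report.overall_sd == pytest.approx(0.02)

    def test_rigid_ground_truth_has_zero_variation(self, clean_scene):
        bundle, truth = clean_scene
        poses = [
            Pose3D(frame=f, points=truth.keypoints3d[f],
                   n_views=np.full(truth.keypoints3d.shape[1], 4))
            for f in range(len(truth.keypoints3d))
        ]
        report = evaluation.segment_lengths(poses, bundle.skeleton)
        assert report.overall_sd < 1e-3
        assert all(sd < 1e-3 for sd in report.sd.values())

    def test_gaussian_perturbation_gives_sd_in_chi2_band(self):
        rng = np.random.default_rng(31)
        sigma, n = 0.01, 200
        lengths = 0.30 + rng.normal(0, sigma, n)
        report = evaluation.segment_lengths(
            _poses_with_lengths(lengths), _two_point_skeleton()
        )
        lo = sigma * np.sqrt(stats.chi2.ppf(0.005, n - 1) / (n - 1))
        hi = sigma * np.sqrt(stats.chi2.ppf(0.995, n - 1) / (n - 1))
        assert lo <= report.sd["seg"] <= hi

    def test_segment_with_single_frame_reported_missing(self):
        poses = _poses_with_lengths([0.3, 0.31])
        poses[1].points[1] = np.nan
        report = evaluation.segment_lengths(poses, _two_point_skeleton())
        assert np.isnan(report.sd["seg"])


def _pose_obs(kps, cam="cam", frame=0):
    kps = np.asarray(kps, dtype=float)
    return PoseObservation(
        camera_id=cam, frame=frame, keypoints=kps, confidence=np.ones(len(kps))
    )


def _square_truth(n_frames=4, side=100.0):
    truth = []
    for f in range(n_frames):
        truth.append(
            _pose_obs(
                [[0, 0], [side, 0], [side, side], [0, side]], frame=f
            )
        )
    return truth


class TestMetrics2D:
    def test_identity_predictions_are_perfect(self):
        truth = _square_truth()
        m = evaluation.metrics_2d(truth, truth)
        assert m.pck == 1.0 and m.map == 1.0 and m.mpjpe == 0.0

    def test_small_constant_offset_keeps_pck_but_shows_in_mpjpe(self):
        truth = _square_truth(side=100.0)
        offset = np.array([3.0, 0.0])  # below the 5 px PCK radius
        pred = [_pose_obs(t.keypoints + offset, frame=t.frame) for t in truth]
        m = evaluation.metrics_2d(pred, truth)
        assert m.pck == 1.0
        assert m.mpjpe == pytest.approx(3.0)

    def test_half_displaced_keypoints_give_half_pck(self):
        truth = _square_truth(side=100.0)
        pred = []
        for t in truth:
            kps = t.keypoints.copy()
            kps[:2] += 40.0  # far beyond the 5 px radius
            pred.append(_pose_obs(kps, frame=t.frame))
        m = evaluation.metrics_2d(pred, truth)
        assert m.pck == pytest.approx(0.5)

    def test_translation_invariance_of_all_metrics(self):
        rng = np.random.default_rng(32)
        truth = _square_truth()
        pred = [
            _pose_obs(t.keypoints + rng.normal(0, 4, t.keypoints.shape),
                      frame=t.frame)
            for t in truth
        ]
        m1 = evaluation.metrics_2d(pred, truth)
        shift = np.array([512.0, -300.0])
        m2 = evaluation.metrics_2d(
            [_pose_obs(p.keypoints + shift, frame=p.frame) for p in pred],
            [_pose_obs(t.keypoints + shift, frame=t.frame) for t in truth],
        )
        assert m1.pck == m2.pck
        assert m1.map == m2.map
        assert m1.mpjpe == pytest.approx(m2.mpjpe)

    def test_mpjpe_matches_brute_force(self):
        rng = np.random.default_rng(33)
        truth = _square_truth(n_frames=6)
        pred = [
            _pose_obs(t.keypoints + rng.normal(0, 10, t.keypoints.shape),
                      frame=t.frame)
            for t in truth
        ]
        m = evaluation.metrics_2d(pred, truth)
        brute = np.mean(
            [
                np.linalg.norm(p.keypoints - t.keypoints, axis=1)
                for p, t in zip(pred, truth)
            ]
        )
        assert m.mpjpe == pytest.approx(brute, rel=1e-12)


def _report_with_mean(mean, sd=0.001):
    sk = _two_point_skeleton()
    return evaluation.SegmentReport(
        lengths={"seg": np.array([mean])},
        sd={"seg": sd},
        mean={"seg": mean},
        overall_sd=sd,
    )


class TestRunLevelComparison:
    def test_identical_methods_give_p_one(self):
        runs = [_report_with_mean(0.30 + 0.001 * i) for i in range(5)]
        out = evaluation.run_level_comparison({"a": runs, "b": list(runs)})
        assert out.wilcoxon_p[("a", "b")] == 1.0

    def test_constant_one_cm_shift_detected(self):
        rng = np.random.default_rng(34)
        base = 0.30 + rng.normal(0, 0.002, 10)
        a = [_report_with_mean(v) for v in base]
        b = [_report_with_mean(v + 0.01) for v in base]
        out = evaluation.run_level_comparison({"a": a, "b": b})
        centre_a = np.mean(out.ci95["a"])
        centre_b = np.mean(out.ci95["b"])
        assert centre_b - centre_a == pytest.approx(0.01, abs=1e-12)
        assert out.wilcoxon_p[("a", "b")] < 0.01

    def test_ci_width_follows_t_over_sqrt_n(self):
        rng = np.random.default_rng(35)
        small = 0.30 + rng.normal(0, 0.002, 10)
        tiled = np.tile(small, 4)
        # rescale so the sample SD matches exactly, isolating the 1/sqrt(n) term
        tiled = tiled.mean() + (tiled - tiled.mean()) * (
            np.std(small, ddof=1) / np.std(tiled, ddof=1)
        )
        out = evaluation.run_level_comparison(
            {"s": [_report_with_mean(v) for v in small]}
            | {"l": [_report_with_mean(v) for v in small]}
        )
        w_small = out.ci95["s"][1] - out.ci95["s"][0]
        out_big = evaluation.run_level_comparison(
            {"s": [_report_with_mean(v) for v in tiled]}
            | {"l": [_report_with_mean(v) for v in tiled]}
        )
        w_big = out_big.ci95["s"][1] - out_big.ci95["s"][0]
        expected_ratio = (stats.t.ppf(0.975, 39) / stats.t.ppf(0.975, 9)) / 2.0
        assert w_big / w_small == pytest.approx(expected_ratio, rel=1e-9)

    def test_unpaired_runs_rejected(self):
        a = [_report_with_mean(0.3)] * 3
        b = [_report_with_mean(0.3)] * 4
        with pytest.raises(ConfigurationError):
            evaluation.run_level_comparison({"a": a, "b": b})


class TestPixelToWorld:
    def test_field_scale_conversion(self):
        # 4.1 px at the skier's 1.5 m / 1080 px scale is ~0.57 cm (≈0.6 cm)
        got = evaluation.pixel_to_world(4.1, 1.5, 1080.0)
        assert got == pytest.approx(0.5694, abs=1e-4)
        assert round(got, 1) == 0.6

    @pytest.mark.parametrize("err,expected", [(0.0, 0.0), (1080.0, 150.0)])
    def test_limit_cases(self, err, expected):
        assert evaluation.pixel_to_world(err, 1.5, 1080.0) == pytest.approx(expected)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluation.pixel_to_world(1.0, 0.0, 1080.0)


def _ref(cam, frame, rid, x, y):
    return RefDetection(
        camera_id=cam,
        frame=frame,
        box=np.array([x - 5, y - 5, x + 5, y + 5]),
        centroid=np.array([x, y], dtype=float),
        ref_id=rid,
    )


class TestRefpointAgreement:
    def test_identical_sets_agree_exactly(self):
        auto = [_ref("A", f, r, 100.0 * r, 50.0) for f in range(3) for r in range(4)]
        out = evaluation.refpoint_agreement(auto, auto)
        assert out.overall_mean == 0.0 and out.outliers == []

    def test_constant_three_pixel_shift(self):
        auto = [_ref("A", f, r, 100.0 * r, 50.0) for f in range(3) for r in range(4)]
        manual = [_ref("A", f, r, 100.0 * r + 3.0, 50.0)
                  for f in range(3) for r in range(4)]
        out = evaluation.refpoint_agreement(auto, manual)
        assert out.overall_mean == pytest.approx(3.0)

    def test_gaussian_annotation_noise_gives_rayleigh_mean(self):
        rng = np.random.default_rng(36)
        sigma, n = 4.0, 4000
        auto = [_ref("A", i, i, 1000.0, 1000.0) for i in range(n)]
        manual = [
            _ref("A", i, i, 1000.0 + rng.normal(0, sigma),
                 1000.0 + rng.normal(0, sigma))
            for i in range(n)
        ]
        out = evaluation.refpoint_agreement(manual, auto, outlier_threshold=50.0)
        mean_r = sigma * np.sqrt(np.pi / 2)
        sd_r = sigma * np.sqrt(2 - np.pi / 2)
        half = 2.576 * sd_r / np.sqrt(n)  # 99% band
        assert mean_r - half <= out.overall_mean <= mean_r + half

    def test_outliers_above_threshold_listed(self):
        auto = [_ref("A", 0, 1, 100.0, 100.0), _ref("A", 0, 2, 300.0, 100.0)]
        manual = [_ref("A", 0, 1, 100.0, 100.0), _ref("A", 0, 2, 400.0, 100.0)]
        out = evaluation.refpoint_agreement(auto, manual)
        assert [(o[2], o[3]) for o in out.outliers] == [(2, pytest.approx(100.0))]
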