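"""DLT estimation: exactness, degeneracy, outlier rejection, trial flow."""

import dataclasses

import numpy as np
import pytest

from ptzmocap import calibration, scene_sim
from ptzmocap.types import (
    Correspondence,
    DegenerateGeometryError,
    InsufficientDataError,
)

from conftest import clean_config, random_camera, random_correspondences


def _matrices_close_up_to_scale(A, B, atol=1e-6):
    a = A / np.linalg.norm(A)
    b = B / np.linalg.norm(B)
    return min(np.abs(a - b).max(), np.abs(a + b).max()) < atol


class TestEstimateDlt:
    def test_exact_recovery_over_many_random_cameras(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            P_true = random_camera(rng)
            corrs = random_correspondences(rng, P_true, n=rng.integers(6, 20))
            P_est = calibration.estimate_dlt(corrs)
            assert _matrices_close_up_to_scale(P_est.P, P_true.P)
            errs = calibration.reprojection_errors(P_est, corrs)
            assert errs.max() < 1e-8

    def test_coplanar_points_are_degenerate(self):
        rng = np.random.default_rng(0)
        P_true = random_camera(rng)
        corrs = []
        for i in range(8):
            world = np.array([rng.uniform(-5, 5), rng.uniform(-5, 5), 2.0])
            uv, _ = P_true.project(world)
            corrs.append(Correspondence(ref_id=i, world=world, image=uv))
        with pytest.raises(DegenerateGeometryError):
            calibration.estimate_dlt(corrs)

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(1)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=5)
        with pytest.raises(InsufficientDataError):
            calibration.estimate_dlt(corrs)

    def test_noise_level_shows_up_as_reprojection_error(self):
        # 1 px image noise on 15 points should give a mean error near 1 px
        rng = np.random.default_rng(2)
        means = []
        for _ in range(50):
            P_true = random_camera(rng)
            corrs = random_correspondences(rng, P_true, n=15)
            noisy = [
                dataclasses.replace(c, image=c.image + rng.normal(0, 1.0, 2))
                for c in corrs
            ]
            P_est = calibration.estimate_dlt(noisy)
            means.append(calibration.reprojection_errors(P_est, noisy).mean())
        assert 0.5 < np.mean(means) < 2.0

    def test_invariant_to_correspondence_ordering(self):
        rng = np.random.default_rng(3)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=12)
        P_a = calibration.estimate_dlt(corrs)
        P_b = calibration.estimate_dlt(list(reversed(corrs)))
        assert _matrices_close_up_to_scale(P_a.P, P_b.P, atol=1e-9)


class TestReprojectionErrors:
    def test_self_consistent_observations_have_zero_error(self):
        rng = np.random.default_rng(4)
        P = random_camera(rng)
        corrs = random_correspondences(rng, P, n=10)
        assert calibration.reprojection_errors(P, corrs).max() < 1e-9

    def test_shifted_observation_error_equals_shift(self):
        rng = np.random.default_rng(5)
        P = random_camera(rng)
        corrs = random_correspondences(rng, P, n=10)
        corrs[3] = dataclasses.replace(
            corrs[3], image=corrs[3].image + np.array([10.0, 0.0])
        )
        errs = calibration.reprojection_errors(P, corrs)
        assert errs[3] == pytest.approx(10.0)

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            P = random_camera(rng)
            c = random_correspondences(rng, P, n=1)[0]
            c = dataclasses.replace(c, image=c.image + rng.normal(0, 5, 2))
            h = P.P @ np.append(c.world, 1.0)
            expected = np.linalg.norm(h[:2] / h[2] - c.image)
            got = calibration.reprojection_errors(P, [c])[0]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_point_behind_camera_flagged_infinite(self):
        rng = np.random.default_rng(7)
        P = random_camera(rng)
        c = random_correspondences(rng, P, n=1)[0]
        # reflect the point through the camera centre to put it behind
        M = P.P
        centre = -np.linalg.inv(M[:, :3]) @ M[:, 3]
        behind = dataclasses.replace(c, world=2 * centre - c.world)
        assert np.isinf(calibration.reprojection_errors(P, [behind])[0])


class TestRejectOutliers:
    def test_single_gross_outlier_removed_exactly(self):
        rng = np.random.default_rng(8)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=20)
        bad = dataclasses.replace(
            corrs[7], ref_id=777, image=corrs[7].image + np.array([100.0, 0.0])
        )
        corrs[7] = bad
        P, inliers, rejected = calibration.reject_outliers(corrs)
        assert rejected == [777]
        assert len(inliers) == 19
        assert calibration.reprojection_errors(P, inliers).max() < 1e-6

    def test_six_points_never_reduced(self):
        rng = np.random.default_rng(9)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=6)
        corrs[0] = dataclasses.replace(
            corrs[0], image=corrs[0].image + np.array([50.0, 0.0])
        )
        _, inliers, rejected = calibration.reject_outliers(corrs)
        assert len(inliers) == 6 and rejected == []

    def test_clean_points_yield_no_rejection(self):
        rng = np.random.default_rng(10)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=12)
        _, inliers, rejected = calibration.reject_outliers(corrs)
        assert rejected == [] and len(inliers) == 12

    def test_mean_error_never_increases_and_floor_holds(self):
        rng = np.random.default_rng(11)
        P_true = random_camera(rng)
        corrs = random_correspondences(rng, P_true, n=10)
        noisy = [
            dataclasses.replace(c, image=c.image + rng.normal(0, 3.0, 2))
            for c in corrs
        ]
        P0 = calibration.estimate_dlt(noisy)
        before = calibration.reprojection_errors(P0, noisy).mean()
        P, inliers, _ = calibration.reject_outliers(noisy)
        after = calibration.reprojection_errors(P, inliers).mean()
        assert after <= before + 1e-12
        assert len(inliers) >= 6


class TestSelectNearest:
    def test_agrees_with_full_sort(self, clean_scene):
        bundle, _ = clean_scene
        rng = np.random.default_rng(12)
        stream = bundle.streams["camA"]
        for f in list(stream.refs)[:20]:
            dets = stream.refs[f]
            centroid = rng.uniform(0, 3840), rng.uniform(0, 2160)
            got = calibration.select_nearest(dets, np.array(centroid), k=15)
            dist = sorted(
                dets, key=lambda d: np.linalg.norm(d.centroid - np.array(centroid))
            )
            expected = {d.ref_id for d in dist[:15]}
            assert {d.ref_id for d in got} == expected

    def test_fewer_than_k_returns_all(self, clean_scene):
        bundle, _ = clean_scene
        dets = list(bundle.streams["camA"].refs[0])[:10]
        got = calibration.select_nearest(dets, np.array([1920.0, 1080.0]), k=15)
        assert len(got) == len(dets)

    def test_missing_centroid_falls_back_to_all(self, clean_scene):
        bundle, _ = clean_scene
        dets = bundle.streams["camA"].refs[0]
        got = calibration.select_nearest(dets, None, k=15)
        assert len(got) == len([d for d in dets if d.ref_id is not None])


class TestCalibrateTrial:
    def test_noise_free_trial_fully_calibrated(self, clean_scene):
        bundle, _ = clean_scene
        matrices, report = calibration.calibrate_trial(bundle)
        for cid, stream in bundle.streams.items():
            assert report.n_calibrated(cid) == len(stream.refs)
            for fc in report.frames[cid].values():
                assert fc.status == "calibrated"
                assert fc.mean_error < 1e-6

    def test_frames_with_too_few_cubes_excluded(self, clean_scene):
        bundle, _ = clean_scene
        stream = bundle.streams["camA"]
        starved = {
            f: (dets[:3] if 10 <= f < 20 else dets)
            for f, dets in stream.refs.items()
        }
        patched = dataclasses.replace(
            bundle,
            streams={
                **bundle.streams,
                "camA": dataclasses.replace(stream, refs=starved),
            },
        )
        _, report = calibration.calibrate_trial(patched)
        for f, fc in report.frames["camA"].items():
            if 10 <= f < 20:
                assert fc.status == "excluded"
            else:
                assert fc.status == "calibrated"

    def test_drifted_cubes_dominate_rejections(self):
        cfg = clean_config(n_frames=30, rng_seed=13)
        bundle, _ = scene_sim.generate_scene(cfg)
        drifted_ids = {5, 11, 23}
        # displace the *survey table* for three cubes by a fixed 16 cm so the
        # rendered detections no longer match their surveyed positions
        table = []
        rng = np.random.default_rng(15)
        for p in bundle.surveyed:
            if p.ref_id in drifted_ids:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                table.append(
                    dataclasses.replace(p, position=p.position + 0.16 * direction)
                )
            else:
                table.append(p)
        patched = dataclasses.replace(bundle, surveyed=table)
        _, report = calibration.calibrate_trial(patched)
        counts = report.rejected_counts()
        assert counts, "drifted cubes should trigger rejections"
        # repeat offenders are exactly the drifted cubes (a drifted cube far
        # from the skier's line may simply never enter the nearest-15 set)
        repeat = {rid for rid, n in counts.items() if n >= 5}
        assert repeat and repeat <= drifted_ids
        assert max(counts[rid] for rid in repeat) >= 10
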