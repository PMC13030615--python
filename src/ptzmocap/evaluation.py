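"""Evaluation metrics for the pipeline's two accuracy questions.

2D: how well do predicted keypoints match reference annotations (PCK, an
OKS-based mAP, MPJPE), and how far do automatic cube centroids sit from
manual ones.  3D: since true anatomical segment lengths are constant, the
standard deviation of each reconstructed segment's length across frames
measures reconstruction consistency independent of annotation error;
across several runs the comparison uses run-wise means with t-based 95%
confidence intervals and run-level Wilcoxon signed-rank tests (frames are
not independent observations).  A seeded 2x2 synthetic experiment emulates
the manual/automatic factor design for reference points and keypoints.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import calibration, reconstruction, scene_sim
from .types import (
    ConfigurationError,
    InsufficientDataError,
    Pose3D,
    PoseObservation,
    RefDetection,
    SceneConfig,
    SkeletonModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentReport",
    "Metrics2D",
    "RunComparison",
    "segment_lengths",
    "metrics_2d",
    "run_level_comparison",
    "pixel_to_world",
    "refpoint_agreement",
    "method_comparison_experiment",
    "DEFAULT_OKS_SIGMAS",
]

#: Standard person-keypoint OKS sigmas; ski/pole endpoints take the ankle
#: value, the whole-body convention's extra points take their usual values.
DEFAULT_OKS_SIGMAS = {
    "nose": 0.026, "left_eye": 0.025, "right_eye": 0.025,
    "left_ear": 0.035, "right_ear": 0.035,
    "left_shoulder": 0.079, "right_shoulder": 0.079,
    "left_elbow": 0.072, "right_elbow": 0.072,
    "left_wrist": 0.062, "right_wrist": 0.062,
    "left_hip": 0.107, "right_hip": 0.107,
    "left_knee": 0.087, "right_knee": 0.087,
    "left_ankle": 0.089, "right_ankle": 0.089,
    "head": 0.035, "neck": 0.079, "hip": 0.107,
    "left_big_toe": 0.068, "right_big_toe": 0.068,
    "left_small_toe": 0.066, "right_small_toe": 0.066,
    "left_heel": 0.066, "right_heel": 0.066,
    "left_ski_tip": 0.089, "right_ski_tip": 0.089,
    "left_ski_tail": 0.089, "right_ski_tail": 0.089,
    "left_pole_tip": 0.089, "right_pole_tip": 0.089,
}


@dataclass
class SegmentReport:
    """Per-segment length statistics across the frames of one run."""

    lengths: dict[str, np.ndarray]  # per-frame lengths, NaN where missing [m]
    sd: dict[str, float]  # sample SD across frames [m]; NaN if < 2 frames
    mean: dict[str, float]  # mean length [m]
    overall_sd: float  # arithmetic mean of the per-segment SDs [m]

    @property
    def overall_mean(self) -> float:
        vals = [v for v in self.mean.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class Metrics2D:
    pck: float
    map: float
    mpjpe: float
    per_keypoint_pck: dict[str, float] = field(default_factory=dict)
    per_keypoint_error: dict[str, float] = field(default_factory=dict)


@dataclass
class RunComparison:
    """Cross-run summary per method plus paired statistical comparisons."""

    run_means: dict[str, np.ndarray]  # method -> per-run overall mean length [m]
    ci95: dict[str, tuple[float, float]]  # method -> t-based 95% CI of run means
    segment_ci95: dict[str, dict[str, tuple[float, float]]]
    wilcoxon_p: dict[tuple[str, str], float]  # method pair -> two-sided p


def segment_lengths(
    poses: Sequence[Pose3D], skeleton: SkeletonModel
) -> SegmentReport:
    """Per-frame segment lengths and their SD across frames.

    A frame contributes to a segment only when both endpoints were
    reconstructed; SD uses the sample (n-1) formula and is reported as NaN
    (missing) for segments with fewer than two valid frames.
    """
    idx = {n: i for i, n in enumerate(skeleton.keypoint_names)}
    lengths: dict[str, np.ndarray] = {}
    sd: dict[str, float] = {}
    mean: dict[str, float] = {}
    for seg, (a, b) in skeleton.segments.items():
        ia, ib = idx[a], idx[b]
        per_frame = np.array(
            [float(np.linalg.norm(p.points[ia] - p.points[ib])) for p in poses]
        )
        lengths[seg] = per_frame
        valid = per_frame[np.isfinite(per_frame)]
        if len(valid) >= 2:
            sd[seg] = float(np.std(valid, ddof=1))
            mean[seg] = float(np.mean(valid))
        else:
            sd[seg] = float("nan")
            mean[seg] = float(np.mean(valid)) if len(valid) else float("nan")
    finite = [v for v in sd.values() if np.isfinite(v)]
    overall = float(np.mean(finite)) if finite else float("nan")
    return SegmentReport(lengths=lengths, sd=sd, mean=mean, overall_sd=overall)


def _truth_scale(truth_kp: np.ndarray) -> tuple[float, float, float]:
    """Reference scale of one instance: bbox max side, width, height."""
    vis = truth_kp[~np.isnan(truth_kp).any(axis=1)]
    w = float(vis[:, 0].max() - vis[:, 0].min())
    h = float(vis[:, 1].max() - vis[:, 1].min())
    return max(w, h), w, h


def metrics_2d(
    pred: Sequence[PoseObservation],
    truth: Sequence[PoseObservation],
    pck_fraction: float = 0.05,
    oks_sigmas: Optional[dict[str, float]] = None,
    keypoint_names: Optional[Sequence[str]] = None,
) -> Metrics2D:
    """PCK, OKS-based mAP and MPJPE over matched frame pairs.

    PCK counts a keypoint correct within ``pck_fraction`` times the larger
    side of the instance's truth bounding box (the box spanned by the
    visible truth keypoints).  mAP averages, over OKS thresholds
    0.50:0.05:0.95, the fraction of instances whose object-keypoint
    similarity clears the threshold.  MPJPE is the mean pixel error over
    keypoints visible in both sets.
    """
    if len(pred) != len(truth) or not pred:
        raise InsufficientDataError("need matched, non-empty prediction/truth lists")
    n_kp = truth[0].keypoints.shape[0]
    names = list(keypoint_names) if keypoint_names else [f"kp{i}" for i in range(n_kp)]
    sig = oks_sigmas or DEFAULT_OKS_SIGMAS
    sigmas = np.array([sig.get(n, 0.089) for n in names])

    correct = np.zeros(n_kp)
    visible = np.zeros(n_kp)
    err_sum = np.zeros(n_kp)
    oks_values = []
    for p, t in zip(pred, truth):
        both = ~(
            np.isnan(p.keypoints).any(axis=1) | np.isnan(t.keypoints).any(axis=1)
        )
        if not both.any():
            continue
        scale, w, h = _truth_scale(t.keypoints)
        d = np.linalg.norm(p.keypoints - t.keypoints, axis=1)
        radius = pck_fraction * scale
        correct[both] += d[both] <= radius
        visible[both] += 1
        err_sum[both] += d[both]
        area = max(w * h, 1.0)
        k2 = (2.0 * sigmas[both]) ** 2
        oks_values.append(float(np.mean(np.exp(-(d[both] ** 2) / (2.0 * area * k2)))))
    if not oks_values:
        raise InsufficientDataError("no frame has keypoints visible in both sets")

    total_vis = visible.sum()
    pck = float(correct.sum() / total_vis)
    mpjpe = float(err_sum.sum() / total_vis)
    thresholds = np.arange(0.50, 0.951, 0.05)
    oks_arr = np.array(oks_values)
    ap = [float(np.mean(oks_arr >= thr)) for thr in thresholds]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pck = {
            names[k]: float(correct[k] / visible[k]) if visible[k] else float("nan")
            for k in range(n_kp)
        }
        per_err = {
            names[k]: float(err_sum[k] / visible[k]) if visible[k] else float("nan")
            for k in range(n_kp)
        }
    return Metrics2D(
        pck=pck,
        map=float(np.mean(ap)),
        mpjpe=mpjpe,
        per_keypoint_pck=per_pck,
        per_keypoint_error=per_err,
    )


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return (m, m)
    half = stats.t.ppf(0.975, n - 1) * float(np.std(values, ddof=1)) / np.sqrt(n)
    return (m - half, m + half)


def run_level_comparison(
    reports: dict[str, Sequence[SegmentReport]]
) -> RunComparison:
    """Compare methods across runs, treating the run as the unit of analysis.

    For each method the per-run overall mean segment length feeds a t-based
    95% CI (and per-segment CIs); each method pair is compared with a
    two-sided Wilcoxon signed-rank test on the paired run values.  Zero
    differences are discarded (standard convention, logged); all-zero
    differences give p = 1.
    """
    methods = sorted(reports)
    n_runs = {m: len(reports[m]) for m in methods}
    if len(set(n_runs.values())) != 1:
        raise ConfigurationError(f"runs are not paired across methods: {n_runs}")
    if next(iter(n_runs.values())) < 2:
        raise InsufficientDataError("need at least two runs per method")

    run_means = {
        m: np.array([r.overall_mean for r in reports[m]]) for m in methods
    }
    ci95 = {m: _t_ci(run_means[m]) for m in methods}
    seg_names = list(next(iter(reports.values()))[0].mean)
    segment_ci95 = {
        m: {
            s: _t_ci(np.array([r.mean[s] for r in reports[m]]))
            for s in seg_names
        }
        for m in methods
    }
    wilcoxon_p: dict[tuple[str, str], float] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            diff = run_means[a] - run_means[b]
            nonzero = diff[diff != 0]
            if len(nonzero) == 0:
                logger.info("methods %s and %s identical on every run", a, b)
                wilcoxon_p[(a, b)] = 1.0
                continue
            if len(nonzero) < len(diff):
                logger.info(
                    "%d zero differences discarded for pair (%s, %s)",
                    len(diff) - len(nonzero), a, b,
                )
            res = stats.wilcoxon(nonzero, alternative="two-sided")
            wilcoxon_p[(a, b)] = float(res.pvalue)
    return RunComparison(
        run_means=run_means,
        ci95=ci95,
        segment_ci95=segment_ci95,
        wilcoxon_p=wilcoxon_p,
    )


def pixel_to_world(err: float, object_height: float, object_height_px: float) -> float:
    """Convert a pixel error to centimetres via a known object scale.

    E.g. a 4.1 px error on a 1.5 m skier imaged at 1080 px is about 0.57 cm.
    """
    if err < 0:
        raise ConfigurationError("error must be >= 0")
    if object_height <= 0 or object_height_px <= 0:
        raise ConfigurationError("scale inputs must be positive")
    return err * (object_height / object_height_px) * 100.0


@dataclass
class RefAgreement:
    overall_mean: float  # mean pixel distance over matched detections
    per_camera: dict[str, float]
    outliers: list[tuple[str, int, int, float]]  # (camera, frame, ref_id, distance)


def refpoint_agreement(
    auto: Sequence[RefDetection],
    manual: Sequence[RefDetection],
    outlier_threshold: float = 50.0,
) -> RefAgreement:
    """Mean pixel distance between automatic and manual cube centroids.

    Detections are matched by (camera, frame, ref_id); matches farther
    apart than ``outlier_threshold`` pixels are listed for inspection
    (in the field such outliers were traced to annotation errors).
    """
    manual_by_key = {
        (d.camera_id, d.frame, d.ref_id): d for d in manual if d.ref_id is not None
    }
    dists: dict[str, list[float]] = {}
    outliers = []
    all_d = []
    for d in auto:
        if d.ref_id is None:
            continue
        m = manual_by_key.get((d.camera_id, d.frame, d.ref_id))
        if m is None:
            continue
        dist = float(np.linalg.norm(d.centroid - m.centroid))
        dists.setdefault(d.camera_id, []).append(dist)
        all_d.append(dist)
        if dist > outlier_threshold:
            outliers.append((d.camera_id, d.frame, d.ref_id, dist))
    if not all_d:
        raise InsufficientDataError("no detections matched between the two sets")
    return RefAgreement(
        overall_mean=float(np.mean(all_d)),
        per_camera={c: float(np.mean(v)) for c, v in dists.items()},
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# 2x2 manual/automatic factor experiment on synthetic data
# ---------------------------------------------------------------------------

def _add_ref_noise(bundle, sd: float, rng: np.random.Generator):
    streams = {}
    for cid, stream in bundle.streams.items():
        s = dataclasses.replace(stream, refs={}, poses=stream.poses,
                                skier_centroid=stream.skier_centroid)
        s.refs = {
            f: [
                dataclasses.replace(
                    d.copy(),
                    centroid=d.centroid + rng.normal(0.0, sd, size=2),
                )
                for d in dets
            ]
            for f, dets in stream.refs.items()
        }
        streams[cid] = s
    return dataclasses.replace(bundle, streams=streams)


def _noisy_poses(
    bundle, sd: float, rng: np.random.Generator
) -> dict[str, dict[int, PoseObservation]]:
    out: dict[str, dict[int, PoseObservation]] = {}
    for cid, stream in bundle.streams.items():
        out[cid] = {}
        for f, pose in stream.poses.items():
            kp = pose.keypoints + rng.normal(0.0, sd, size=pose.keypoints.shape)
            out[cid][f] = PoseObservation(cid, f, kp, pose.confidence.copy())
    return out


def method_comparison_experiment(
    seed: int,
    ref_noise: dict[str, float] | None = None,
    kp_noise: dict[str, float] | None = None,
    n_frames: int = 50,
    n_cameras: int = 4,
    n_refpoints: int = 60,
) -> dict[tuple[str, str], float]:
    """One seeded replicate of the 2x2 reference-by-keypoint factor design.

    A noise-free scene is rendered once; "automatic" and "manual" streams
    are emulated by adding annotation noise of different magnitude to the
    cube centroids (calibration factor) and keypoints (reconstruction
    factor).  Each of the four combinations is calibrated, reconstructed,
    smoothed and scored by overall segment-length SD.  Returns
    ``{(ref_method, kp_method): overall SD in metres}``.
    """
    ref_noise = ref_noise or {"automatic": 1.0, "manual": 4.0}
    kp_noise = kp_noise or {"automatic": 2.0, "manual": 5.0}
    config = SceneConfig(
        n_cameras=n_cameras,
        n_refpoints=n_refpoints,
        n_frames=n_frames,
        pixel_noise_sd=0.0,
        ref_dropout_prob=0.0,
        id_dropout_prob=0.0,
        keypoint_noise_sd=0.0,
        rng_seed=seed,
    )
    bundle, _ = scene_sim.generate_scene(config)
    rng = np.random.default_rng(seed + 2**20)

    matrices_by_ref = {}
    for ref_method, sd in ref_noise.items():
        noisy = _add_ref_noise(bundle, sd, rng)
        matrices_by_ref[ref_method], _ = calibration.calibrate_trial(noisy)
    poses_by_kp = {
        kp_method: _noisy_poses(bundle, sd, rng) for kp_method, sd in kp_noise.items()
    }

    cams = sorted(bundle.streams)
    results: dict[tuple[str, str], float] = {}
    for ref_method, matrices in matrices_by_ref.items():
        for kp_method, poses in poses_by_kp.items():
            recon = reconstruction.reconstruct_trial(
                poses, matrices, cams, n_frames=config.n_frames
            )
            smoothed = reconstruction.smooth(
                recon, sample_rate=config.frame_rate
            )
            report = segment_lengths(smoothed, bundle.skeleton)
            results[(ref_method, kp_method)] = report.overall_sd
    return results
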