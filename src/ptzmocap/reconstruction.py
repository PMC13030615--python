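"""Multi-view triangulation, trial-wide camera-subset choice, smoothing.

Each keypoint seen in two or more calibrated views yields a homogeneous
linear system (two rows per view, the same algebraic form as the
calibration residuals) whose SVD null-space vector is the 3D point.  For
temporal stability the same camera subset is used for all frames of a
trial; the subset is found by exhaustively reconstructing with every
combination of >= 2 cameras and keeping the one with the lowest mean
reprojection error into its own views.  Reconstructed trajectories are
finished with a zero-phase 4th-order Butterworth low-pass at 10 Hz.
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .types import (
    ConfigurationError,
    InsufficientDataError,
    Pose3D,
    PoseObservation,
    ProjectionMatrix,
    SubsetChoice,
)

logger = logging.getLogger(__name__)

__all__ = [
    "triangulate",
    "select_subset",
    "reconstruct_trial",
    "smooth",
    "MAX_SUBSET_CAMERAS",
]

MAX_SUBSET_CAMERAS = 8  # exhaustive search stays tractable (<= 247 subsets)
_STABILITY_TOL = 1e-10  # relative size of the second-smallest singular value
_TIE_TOL_PX = 1e-6  # subset scores closer than this count as tied


def triangulate(
    observations: Sequence[tuple[ProjectionMatrix, np.ndarray]],
    confidences: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, bool]:
    """World point from >= 2 (projection matrix, image point) pairs.

    Stacks two rows per view, ``u p3 - p1`` and ``v p3 - p2`` (rows scaled
    to unit norm for conditioning), and takes the SVD null-space vector.
    Returns the dehomogenized point and a stability flag; the flag is False
    for near-parallel rays (the two smallest singular values both vanish
    relative to the largest).  Optional per-view confidence weights scale
    each view's rows.
    """
    if len(observations) < 2:
        raise InsufficientDataError("triangulation needs at least two views")
    rows = []
    for i, (P, uv) in enumerate(observations):
        M = P.P
        u, v = np.asarray(uv, dtype=float)
        w = 1.0 if confidences is None else float(confidences[i])
        for r in (u * M[2] - M[0], v * M[2] - M[1]):
            norm = np.linalg.norm(r)
            if norm > 0:
                rows.append(w * r / norm)
    A = np.stack(rows)
    _, s, Vt = np.linalg.svd(A)
    stable = s[-2] >= _STABILITY_TOL * s[0]
    X = Vt[-1]
    if abs(X[3]) < 1e-14:
        return X[:3], False
    return X[:3] / X[3], bool(stable)


def _reprojection_error(P: ProjectionMatrix, world: np.ndarray, uv: np.ndarray) -> float:
    proj, depth = P.project(world)
    if depth <= 0:
        return np.inf
    return float(np.linalg.norm(proj - uv))


def _frame_observations(
    poses: dict[str, dict[int, PoseObservation]],
    matrices: dict[str, dict[int, ProjectionMatrix]],
    cameras: Sequence[str],
    frame: int,
    keypoint: int,
) -> list[tuple[str, ProjectionMatrix, np.ndarray]]:
    obs = []
    for cid in cameras:
        P = matrices.get(cid, {}).get(frame)
        pose = poses.get(cid, {}).get(frame)
        if P is None or pose is None:
            continue
        uv = pose.keypoints[keypoint]
        if np.any(np.isnan(uv)):
            continue
        obs.append((cid, P, uv))
    return obs


def select_subset(
    poses: dict[str, dict[int, PoseObservation]],
    matrices: dict[str, dict[int, ProjectionMatrix]],
    candidates: Optional[Sequence[str]] = None,
    return_scores: bool = False,
):
    """Exhaustive search for the camera subset with the lowest self-consistent
    reprojection error, fixed for the whole trial.

    Every subset of size >= 2 is scored by triangulating all keypoints over
    all frames from the subset's own views and averaging the reprojection
    error back into those views.  Ties (within numerical tolerance) go to
    the larger subset, then lexicographically.  With ``return_scores`` the
    full scored list of evaluated subsets is returned alongside the choice.
    """
    cams = sorted(candidates if candidates is not None else matrices)
    if len(cams) < 2:
        raise InsufficientDataError("need at least two candidate cameras")
    if len(cams) > MAX_SUBSET_CAMERAS:
        raise ConfigurationError(
            f"exhaustive subset search is capped at {MAX_SUBSET_CAMERAS} cameras"
        )
    frames = sorted({f for cid in cams for f in poses.get(cid, {})})
    n_kp = None
    for cid in cams:
        for pose in poses.get(cid, {}).values():
            n_kp = pose.keypoints.shape[0]
            break
        if n_kp is not None:
            break
    if n_kp is None:
        raise InsufficientDataError("no pose observations among the candidates")

    scored: list[SubsetChoice] = []
    for size in range(2, len(cams) + 1):
        for subset in itertools.combinations(cams, size):
            errors: list[float] = []
            for f in frames:
                for k in range(n_kp):
                    obs = _frame_observations(poses, matrices, subset, f, k)
                    if len(obs) < 2:
                        continue
                    world, stable = triangulate([(P, uv) for _, P, uv in obs])
                    if not stable:
                        continue
                    errors.extend(
                        _reprojection_error(P, world, uv) for _, P, uv in obs
                    )
            if errors:
                scored.append(SubsetChoice(subset, float(np.mean(errors))))
    if not scored:
        raise InsufficientDataError("no camera subset yields two views of any keypoint")
    best = min(c.mean_error for c in scored)
    tied = [c for c in scored if c.mean_error <= best + _TIE_TOL_PX]
    tied.sort(key=lambda c: (-len(c.cameras), c.cameras))
    choice = tied[0]
    logger.info(
        "selected cameras %s (mean reprojection error %.3f px, %d subsets scored)",
        choice.cameras,
        choice.mean_error,
        len(scored),
    )
    if return_scores:
        return choice, scored
    return choice


def reconstruct_trial(
    poses: dict[str, dict[int, PoseObservation]],
    matrices: dict[str, dict[int, ProjectionMatrix]],
    subset: Sequence[str],
    n_frames: Optional[int] = None,
    use_confidence_weights: bool = False,
) -> list[Pose3D]:
    """Triangulate every keypoint of every frame from the fixed subset.

    Keypoints observed in fewer than two calibrated subset views are left
    missing (NaN) for that frame; gaps are recorded, never fatal.
    """
    subset = sorted(subset)
    frames = (
        range(n_frames)
        if n_frames is not None
        else sorted({f for cid in subset for f in poses.get(cid, {})})
    )
    n_kp = None
    for cid in subset:
        for pose in poses.get(cid, {}).values():
            n_kp = pose.keypoints.shape[0]
            break
        if n_kp:
            break
    if n_kp is None:
        raise InsufficientDataError("no pose observations in the chosen subset")

    out = []
    for f in frames:
        pts = np.full((n_kp, 3), np.nan)
        n_views = np.zeros(n_kp, dtype=int)
        for k in range(n_kp):
            obs = _frame_observations(poses, matrices, subset, f, k)
            if len(obs) < 2:
                continue
            conf = None
            if use_confidence_weights:
                conf = [
                    float(poses[cid][f].confidence[k]) for cid, _, _ in obs
                ]
            world, stable = triangulate([(P, uv) for _, P, uv in obs], conf)
            if not stable:
                continue
            pts[k] = world
            n_views[k] = len(obs)
        out.append(Pose3D(frame=f, points=pts, n_views=n_views))
    n_missing = sum(int(np.sum(p.n_views == 0)) for p in out)
    logger.info(
        "reconstructed %d frames (%d keypoint gaps)", len(out), n_missing
    )
    return out


def _filter_series(
    x: np.ndarray, b: np.ndarray, a: np.ndarray, max_gap: int
) -> np.ndarray:
    """Zero-phase filter one coordinate series with NaN-gap handling:
    interior gaps <= max_gap are bridged by linear interpolation for the
    filter pass and re-masked afterwards; longer gaps and edge gaps split
    the series into independently filtered runs."""
    n = len(x)
    out = np.full(n, np.nan)
    mask = np.isnan(x)
    valid = np.nonzero(~mask)[0]
    if len(valid) == 0:
        return out
    # split where a gap is too long to bridge
    splits = [0]
    for i in range(1, len(valid)):
        if valid[i] - valid[i - 1] - 1 > max_gap:
            splits.append(i)
    splits.append(len(valid))
    for s, e in zip(splits[:-1], splits[1:]):
        lo, hi = valid[s], valid[e - 1]
        seg = x[lo : hi + 1].copy()
        seg_mask = np.isnan(seg)
        if seg_mask.any():
            idx = np.arange(len(seg))
            seg[seg_mask] = np.interp(idx[seg_mask], idx[~seg_mask], seg[~seg_mask])
        if len(seg) <= 3 * max(len(a), len(b)):
            filtered = seg  # too short for stable zero-phase filtering
        else:
            filtered = signal.filtfilt(b, a, seg)
        filtered[seg_mask] = np.nan
        out[lo : hi + 1] = filtered
    return out


def smooth(
    poses: Sequence[Pose3D],
    cutoff: float = 10.0,
    sample_rate: float = 25.0,
    order: int = 4,
    max_gap: int = 5,
) -> list[Pose3D]:
    """Zero-phase Butterworth low-pass over the 3D keypoint trajectories.

    Forward-backward application doubles the effective order's attenuation
    and cancels phase lag, standard practice for joint kinematics.  Missing
    spans up to ``max_gap`` frames are linearly bridged for filtering and
    re-masked after; longer spans stay missing.
    """
    if cutoff >= sample_rate / 2.0:
        raise ConfigurationError("cutoff must be below the Nyquist frequency")
    if not poses:
        return []
    b, a = signal.butter(order, cutoff / (sample_rate / 2.0))
    n_kp = poses[0].points.shape[0]
    stack = np.stack([p.points for p in poses])  # (n_frames, K, 3)
    smoothed = np.empty_like(stack)
    for k in range(n_kp):
        for c in range(3):
            smoothed[:, k, c] = _filter_series(stack[:, k, c], b, a, max_gap)
    return [
        Pose3D(frame=p.frame, points=smoothed[i], n_views=p.n_views.copy())
        for i, p in enumerate(poses)
    ]
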