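"""Frame-wise DLT camera calibration for pan-tilt-zoom cameras.

A camera that pans, tilts and zooms has a different projection matrix in
every frame, so the 3x4 matrix P mapping surveyed world positions to image
pixels is re-estimated per frame by the Direct Linear Transformation: each
correspondence (X, (u, v)) contributes the two homogeneous equations

    u (p3 . X) - p1 . X = 0
    v (p3 . X) - p2 . X = 0

and the stacked system is solved for the null-space vector by SVD, with
Hartley-style isotropic pre-normalization of both point sets for
conditioning.  Around the estimate sit the field-protocol guards: only the
15 reference points nearest the skier are used, points introducing large
reprojection errors are removed iteratively while the mean error improves
by at least 5%, and frames left with fewer than six valid points are
excluded.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .types import (
    CalibrationReport,
    Correspondence,
    DegenerateGeometryError,
    FrameCalibration,
    InsufficientDataError,
    ProjectionMatrix,
    RefDetection,
    TrialBundle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_dlt",
    "reprojection_errors",
    "reject_outliers",
    "select_nearest",
    "calibrate_trial",
    "MIN_POINTS",
    "NEAREST_K",
    "IMPROVEMENT_THRESHOLD",
]

MIN_POINTS = 6  # a frame with fewer valid reference points is excluded
NEAREST_K = 15  # reference points used per frame, nearest to the skier
IMPROVEMENT_THRESHOLD = 0.05  # relative mean-error gain required to keep removing
_ERROR_FLOOR_PX = 1e-9  # below this the mean error is round-off; stop removing
_DEGENERACY_TOL = 1e-8  # rank test on the normalized design matrix


def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    return (pts - centroid) * s, T


def _normalize_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(3.0) / d if d > 0 else 1.0
    U = np.eye(4)
    U[:3, :3] *= s
    U[:3, 3] = -s * centroid
    return (pts - centroid) * s, U


def estimate_dlt(
    corrs: Sequence[Correspondence], camera_id: str = "", frame: int = -1
) -> ProjectionMatrix:
    """Estimate the 3x4 projection matrix from >= 6 correspondences.

    The returned matrix is scaled to unit Frobenius norm with its sign
    chosen so the calibration points have positive projective depth.

    Raises :class:`InsufficientDataError` below six points and
    :class:`DegenerateGeometryError` when the points do not determine a
    unique matrix (e.g. all points coplanar).
    """
    if len(corrs) < MIN_POINTS:
        raise InsufficientDataError(
            f"DLT needs at least {MIN_POINTS} points, got {len(corrs)}"
        )
    world = np.stack([c.world for c in corrs])
    image = np.stack([c.image for c in corrs])
    wn, U = _normalize_3d(world)
    im, T = _normalize_2d(image)

    n = len(corrs)
    Xh = np.hstack([wn, np.ones((n, 1))])
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -im[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -im[:, 1:2] * Xh

    _, s, Vt = np.linalg.svd(A)
    # a unique solution has exactly one (near-)zero singular value; a second
    # vanishing one means the configuration is degenerate (coplanar points)
    if s[-2] < _DEGENERACY_TOL * s[0]:
        raise DegenerateGeometryError(
            "point configuration is degenerate (coplanar or near-coplanar)"
        )
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T) @ Pn @ U
    P /= np.linalg.norm(P)
    depths = P[2] @ np.hstack([world, np.ones((n, 1))]).T
    if np.median(depths) < 0:
        P = -P
    return ProjectionMatrix(P=P, camera_id=camera_id, frame=frame)


def reprojection_errors(
    P: ProjectionMatrix, corrs: Sequence[Correspondence]
) -> np.ndarray:
    """Pixel distance between each observation and its reprojected survey
    position; points with non-positive depth get an infinite error."""
    world = np.stack([c.world for c in corrs])
    image = np.stack([c.image for c in corrs])
    proj, depth = P.project(world)
    err = np.linalg.norm(proj - image, axis=1)
    err[depth <= 0] = np.inf
    return err


def reject_outliers(
    corrs: Sequence[Correspondence],
    improvement_threshold: float = IMPROVEMENT_THRESHOLD,
    min_points: int = MIN_POINTS,
    camera_id: str = "",
    frame: int = -1,
) -> tuple[ProjectionMatrix, list[Correspondence], list[int]]:
    """Iteratively remove points that degrade the calibration.

    Each round tentatively drops the worst-reprojecting point and refits;
    the removal sticks only if the mean reprojection error of the remaining
    set falls by at least ``improvement_threshold`` (relative).  Removal
    also stops at ``min_points`` remaining, or once the mean error is at
    numerical round-off.
    """
    current = list(corrs)
    P = estimate_dlt(current, camera_id, frame)
    errs = reprojection_errors(P, current)
    mean_err = float(np.mean(errs))
    rejected: list[int] = []
    while len(current) > min_points and mean_err > _ERROR_FLOOR_PX:
        worst = int(np.argmax(errs))
        trial = current[:worst] + current[worst + 1 :]
        try:
            P_trial = estimate_dlt(trial, camera_id, frame)
        except DegenerateGeometryError:
            break
        errs_trial = reprojection_errors(P_trial, trial)
        mean_trial = float(np.mean(errs_trial))
        if mean_err - mean_trial >= improvement_threshold * mean_err:
            rejected.append(current[worst].ref_id)
            current, P, errs, mean_err = trial, P_trial, errs_trial, mean_trial
        else:
            break
    return P, current, rejected


def select_nearest(
    refs: Sequence[RefDetection],
    skier_centroid: Optional[np.ndarray],
    k: int = NEAREST_K,
) -> list[RefDetection]:
    """The k identified detections nearest the skier in the image.

    Calibration accuracy matters most where the skier is, so only the
    nearest reference points are used.  With no skier centroid available
    all identified detections are returned (logged).
    """
    identified = [d for d in refs if d.ref_id is not None]
    if skier_centroid is None:
        logger.info("no skier centroid; using all %d identified refs", len(identified))
        return identified
    if len(identified) <= k:
        return identified
    c = np.asarray(skier_centroid, dtype=float)
    dist = np.array([np.linalg.norm(d.centroid - c) for d in identified])
    order = np.argpartition(dist, k)[:k]
    return [identified[i] for i in sorted(order, key=lambda i: dist[i])]


def calibrate_trial(
    bundle: TrialBundle,
    k: int = NEAREST_K,
    improvement_threshold: float = IMPROVEMENT_THRESHOLD,
    min_points: int = MIN_POINTS,
) -> tuple[dict[str, dict[int, ProjectionMatrix]], CalibrationReport]:
    """Frame-wise calibration of every camera in a trial.

    Per camera and frame: take the identified reference detections, keep
    the ``k`` nearest the skier, look their world positions up in the
    surveyed table, run outlier rejection, and record either the matrix or
    the exclusion (fewer than ``min_points`` valid points, or degenerate
    geometry).  Per-frame failures are recorded, never fatal.
    """
    table = bundle.surveyed_table()
    matrices: dict[str, dict[int, ProjectionMatrix]] = {}
    report = CalibrationReport()
    for cid, stream in bundle.streams.items():
        matrices[cid] = {}
        report.frames[cid] = {}
        for f, dets in sorted(stream.refs.items()):
            selected = select_nearest(dets, stream.skier_centroid.get(f), k)
            corrs = [
                Correspondence(ref_id=d.ref_id, world=table[d.ref_id], image=d.centroid)
                for d in selected
                if d.ref_id in table
            ]
            if len(corrs) < min_points:
                report.frames[cid][f] = FrameCalibration(status="excluded")
                continue
            try:
                P, inliers, rejected = reject_outliers(
                    corrs, improvement_threshold, min_points, cid, f
                )
            except DegenerateGeometryError:
                report.frames[cid][f] = FrameCalibration(status="degenerate")
                continue
            mean_err = float(np.mean(reprojection_errors(P, inliers)))
            matrices[cid][f] = P
            report.frames[cid][f] = FrameCalibration(
                status="calibrated",
                used_ids=tuple(c.ref_id for c in inliers),
                rejected_ids=tuple(rejected),
                mean_error=mean_err,
            )
        logger.info(
            "camera %s: %d frames calibrated, %d excluded",
            cid,
            report.n_calibrated(cid),
            report.n_excluded(cid),
        )
    return matrices, report
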