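"""Sub-frame camera synchronization from drop-cube traces.

Consumer camcorders have no genlock, so each camera's frame grid is shifted
by an unknown fraction of a frame.  At carving speed that matters: a
half-frame offset at 25 fps moves a 15 m/s skier 30 cm.  The remedy is a
shared physical event — a cube dropped along a rod — whose vertical pixel
trace every camera records.  Free fall and the first bounce are each exact
parabolas; fitting a quadratic to either phase and intersecting the two
pins the impact instant far below single-frame resolution.  Event times per
camera then give fractional offsets, and detection streams are linearly
interpolated onto the reference camera's timeline.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .types import (
    CameraStream,
    ConfigurationError,
    DropTrack,
    InsufficientDataError,
    NoEventError,
    PoseObservation,
    RefDetection,
    SyncResult,
)

logger = logging.getLogger(__name__)

__all__ = [
    "segment_phases",
    "fit_sync_event",
    "compute_offsets",
    "combine_repetitions",
    "resample_stream",
    "synchronize_bundle",
    "displacement_bound",
]

#: per-frame displacement below which the cube counts as "at rest" [px]
_MOVE_THRESHOLD = 1.5
#: repetition-to-repetition offset discrepancy that triggers a warning [frames]
_REPEAT_WARN = 0.2


def segment_phases(
    track: DropTrack, move_threshold: float = _MOVE_THRESHOLD
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the free-fall and first-bounce sample windows of a drop trace.

    Detection follows the trace's curvature and velocity structure: the
    vertical coordinate (growing downward) rises during the fall, reverses
    at impact, and rises again after the bounce apex.  Returns two disjoint
    index windows ``(start, stop)`` (inclusive) bracketing the impact; the
    sample adjacent to the velocity reversal is assigned to neither phase
    because the impact instant generally falls between samples.

    Raises :class:`NoEventError` when the trace has no fall-then-bounce
    structure (e.g. a single parabola with no velocity reversal).
    """
    y = np.asarray(track.y, dtype=float)
    n = len(y)
    if n < 8:
        raise NoEventError("track too short for event fitting")
    d1 = np.diff(y)

    # impact = the first downward-to-upward velocity reversal.  The reversal
    # threshold scales with the peak fall speed so that rest-phase jitter
    # can never fake a reversal, while a real impact (speeds near the peak
    # on both sides) always clears it.
    thr_rev = max(move_threshold, 0.25 * float(np.max(d1)))
    cands = [
        j
        for j in range(1, n - 1)
        if d1[j] < -thr_rev and np.max(d1[max(0, j - 3) : j]) > thr_rev
    ]
    if not cands:
        raise NoEventError("no fall-then-bounce velocity reversal in track")
    j = cands[0]
    # apex sample: the higher of the two samples around the reversal; its
    # side of the impact is ambiguous, so it joins neither window
    m = j if y[j] >= y[j - 1] else j - 1

    # trim the leading rest phase (cube held at the top of the rod); the
    # trim threshold scales with the peak fall speed so rest-phase noise
    # cannot pass as motion.  The first clearly moving sample's predecessor
    # may straddle the release instant, so the window starts one later.
    thr_trim = max(move_threshold, 0.1 * float(np.max(d1)))
    moving = np.nonzero(d1[:m] > thr_trim)[0]
    if len(moving) == 0:
        raise NoEventError("no free-fall motion before the reversal")
    fall = (int(moving[0]) + 1, m - 1)
    bounce = (m + 1, n - 1)
    if fall[1] - fall[0] + 1 < 3 or bounce[1] - bounce[0] + 1 < 3:
        raise NoEventError("a flight phase has fewer than three samples")
    return fall, bounce


def fit_sync_event(track: DropTrack, move_threshold: float = _MOVE_THRESHOLD) -> float:
    """Sub-frame event time of a drop trace, in this camera's frame units.

    Fits one least-squares quadratic to each flight phase and returns the
    intersection root that lies between the phases; with two admissible
    roots the one nearer the inter-window midpoint wins.
    """
    (f0, f1), (b0, b1) = segment_phases(track, move_threshold)
    frames = np.asarray(track.frames, dtype=float)
    y = np.asarray(track.y, dtype=float)
    # centre the abscissa for conditioning
    x0 = frames[f1]
    qf = np.polyfit(frames[f0 : f1 + 1] - x0, y[f0 : f1 + 1], 2)
    qb = np.polyfit(frames[b0 : b1 + 1] - x0, y[b0 : b1 + 1], 2)
    roots = np.roots(qf - qb)
    roots = roots[np.abs(roots.imag) < 1e-9].real + x0

    lo, hi = frames[f1], frames[b0]
    admissible = [r for r in roots if lo <= r <= hi]
    if not admissible:
        raise NoEventError("phase quadratics do not intersect between the windows")
    mid = 0.5 * (lo + hi)
    return float(min(admissible, key=lambda r: abs(r - mid)))


def compute_offsets(events: dict[str, float]) -> SyncResult:
    """Fractional frame offsets relative to the lexicographically first camera."""
    if len(events) < 2:
        raise InsufficientDataError("need events from at least two cameras")
    if not all(math.isfinite(e) for e in events.values()):
        raise ConfigurationError("event times must be finite")
    ref = min(events)
    return SyncResult(
        reference=ref,
        events=dict(events),
        offsets={c: e - events[ref] for c, e in events.items()},
    )


def combine_repetitions(
    results: list[SyncResult], warn_threshold: float = _REPEAT_WARN
) -> SyncResult:
    """Average the offsets of repeated synchronization drops.

    The field protocol drops the cube twice per session; offsets are
    averaged and a discrepancy beyond ``warn_threshold`` frames between
    repetitions is logged as a warning.
    """
    if not results:
        raise InsufficientDataError("no synchronization results to combine")
    ref = results[0].reference
    cameras = set(results[0].offsets)
    for r in results[1:]:
        if r.reference != ref or set(r.offsets) != cameras:
            raise ConfigurationError("repetitions cover different cameras")
    offsets = {}
    for c in cameras:
        vals = [r.offsets[c] for r in results]
        spread = max(vals) - min(vals)
        if spread > warn_threshold:
            logger.warning(
                "camera %s: sync repetitions disagree by %.3f frames", c, spread
            )
        offsets[c] = float(np.mean(vals))
    events = {c: float(np.mean([r.events[c] for r in results])) for c in cameras}
    return SyncResult(reference=ref, events=events, offsets=offsets)


def _lerp_refs(
    prev: list[RefDetection], nxt: list[RefDetection], frac: float, frame: int
) -> list[RefDetection]:
    by_id = {d.ref_id: d for d in nxt if d.ref_id is not None}
    out = []
    for d in prev:
        if d.ref_id is None or d.ref_id not in by_id:
            continue
        e = by_id[d.ref_id]
        out.append(
            RefDetection(
                camera_id=d.camera_id,
                frame=frame,
                box=(1 - frac) * d.box + frac * e.box,
                centroid=(1 - frac) * d.centroid + frac * e.centroid,
                confidence=min(d.confidence, e.confidence),
                ref_id=d.ref_id,
                provenance=d.provenance if d.provenance == e.provenance else "recovered",
            )
        )
    return out


def _lerp_pose(
    prev: PoseObservation, nxt: PoseObservation, frac: float, frame: int
) -> PoseObservation:
    both = ~(np.isnan(prev.keypoints).any(axis=1) | np.isnan(nxt.keypoints).any(axis=1))
    kp = np.full_like(prev.keypoints, np.nan)
    kp[both] = (1 - frac) * prev.keypoints[both] + frac * nxt.keypoints[both]
    conf = np.zeros_like(prev.confidence)
    conf[both] = np.minimum(prev.confidence[both], nxt.confidence[both])
    return PoseObservation(
        camera_id=prev.camera_id, frame=frame, keypoints=kp, confidence=conf
    )


def resample_stream(
    stream: CameraStream, offset: float, n_frames: int
) -> CameraStream:
    """Interpolate a camera's detections onto the reference timeline.

    Output frame ``f`` is the stream evaluated at its own frame coordinate
    ``f + offset``, linearly interpolated between the two neighbouring
    frames.  A point is produced only where both neighbours exist and carry
    the same identity (ref_id or keypoint label); confidences take the
    minimum of the neighbours.  ``offset == 0`` returns an exact copy.
    """
    out = CameraStream(camera_id=stream.camera_id)
    for f in range(n_frames):
        pos = f + offset
        lo = math.floor(pos)
        frac = pos - lo
        if frac == 0.0:
            if lo in stream.refs:
                out.refs[f] = [
                    dataclasses.replace(d.copy(), frame=f) for d in stream.refs[lo]
                ]
            if lo in stream.poses:
                p = stream.poses[lo]
                out.poses[f] = PoseObservation(
                    p.camera_id, f, p.keypoints.copy(), p.confidence.copy()
                )
            if lo in stream.skier_centroid:
                out.skier_centroid[f] = stream.skier_centroid[lo].copy()
            continue
        hi = lo + 1
        if lo in stream.refs and hi in stream.refs:
            out.refs[f] = _lerp_refs(stream.refs[lo], stream.refs[hi], frac, f)
        if lo in stream.poses and hi in stream.poses:
            out.poses[f] = _lerp_pose(stream.poses[lo], stream.poses[hi], frac, f)
        if lo in stream.skier_centroid and hi in stream.skier_centroid:
            out.skier_centroid[f] = (1 - frac) * stream.skier_centroid[
                lo
            ] + frac * stream.skier_centroid[hi]
    return out


def synchronize_bundle(bundle, sync: SyncResult):
    """Resample every camera of a trial onto the reference timeline in place
    of the original streams (returns a new bundle; input is untouched)."""
    streams = {}
    for cid, stream in bundle.streams.items():
        off = sync.offsets.get(cid, 0.0)
        streams[cid] = resample_stream(stream, off, bundle.config.n_frames)
    return dataclasses.replace(bundle, streams=streams)


def displacement_bound(speed: float, frame_rate: float) -> float:
    """Worst-case positional error of a half-frame offset, in metres.

    ``speed * (1 / (2 * frame_rate))`` — e.g. 15 m/s at 25 Hz gives 0.30 m,
    which is why sub-frame synchronization is needed at all.
    """
    if frame_rate <= 0:
        raise ConfigurationError("frame_rate must be positive")
    if speed < 0:
        raise ConfigurationError("speed must be >= 0")
    return speed / (2.0 * frame_rate)
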