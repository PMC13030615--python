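"""Reference-cube association: overlap filtering, localisation-to-identity
matching, and temporal identity recovery.

In the field, cube *localisation* (a box detector) and *identification*
(fiducial decoding) are separate, fallible channels.  This module fuses
them: overlapping boxes are discarded as ambiguous, each decoded marker is
assigned to the box containing it, and identities lost to blur or occlusion
are recovered by shifting the previous frame's identified centroids with a
robust inter-frame image-shift vector and matching them to still-unknown
boxes.  Detector training and pixel-level marker decoding are out of scope;
the inputs here are detection streams.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import RefDetection

logger = logging.getLogger(__name__)

__all__ = [
    "iou",
    "discard_overlaps",
    "match_ids",
    "estimate_shift",
    "temporal_recover",
    "identify_stream",
]


def iou(box_a: np.ndarray, box_b: np.ndarray) -> float:
    """Intersection over union of two (x_min, y_min, x_max, y_max) boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def discard_overlaps(
    boxes: Sequence[RefDetection], threshold: float = 0.5
) -> list[RefDetection]:
    """Drop every detection involved in a pairwise overlap above threshold.

    Both members of an overlapping pair are removed: when two cube boxes
    overlap that much their identities cannot be trusted apart.  The
    comparison is strict (IoU exactly at the threshold is kept).
    """
    n = len(boxes)
    bad = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if iou(boxes[i].box, boxes[j].box) > threshold:
                bad[i] = bad[j] = True
    return [b for i, b in enumerate(boxes) if not bad[i]]


def _contains(box: np.ndarray, point: np.ndarray) -> bool:
    return box[0] <= point[0] <= box[2] and box[1] <= point[1] <= box[3]


def match_ids(
    boxes: Sequence[RefDetection],
    identifications: Iterable[tuple[int, np.ndarray]],
) -> list[RefDetection]:
    """Assign decoded marker identities to the boxes containing them.

    A cube counts as correctly detected only when both channels agree: the
    marker centroid must fall inside a localisation box.  A marker inside
    several boxes goes to the one with the nearest centroid; a box holding
    two different identities is discarded as a conflict; boxes containing
    no marker stay unknown.
    """
    assigned: dict[int, list[int]] = {}  # box index -> distinct ref_ids inside
    for ref_id, marker in identifications:
        marker = np.asarray(marker, dtype=float)
        inside = [i for i, b in enumerate(boxes) if _contains(b.box, marker)]
        if not inside:
            continue
        best = min(inside, key=lambda i: float(np.linalg.norm(boxes[i].centroid - marker)))
        ids = assigned.setdefault(best, [])
        if ref_id not in ids:
            ids.append(ref_id)
    out = []
    for i, b in enumerate(boxes):
        ids = assigned.get(i, [])
        if len(ids) > 1:
            logger.debug("box %d holds conflicting ids %s; discarded", i, ids)
            continue
        d = b.copy()
        d.ref_id = ids[0] if ids else None
        out.append(d)
    return out


def estimate_shift(
    prev: Sequence[RefDetection], curr: Sequence[RefDetection]
) -> Optional[np.ndarray]:
    """Inter-frame image shift from cubes identified in both frames.

    Component-wise median of the centroid displacements over common ids —
    robust to a single mis-tracked cube.  Returns None when the frames share
    no identity (temporal recovery is then skipped for this frame).
    """
    prev_by_id = {d.ref_id: d for d in prev if d.ref_id is not None}
    moves = [
        c.centroid - prev_by_id[c.ref_id].centroid
        for c in curr
        if c.ref_id is not None and c.ref_id in prev_by_id
    ]
    if not moves:
        return None
    return np.median(np.stack(moves), axis=0)


def temporal_recover(
    prev: Sequence[RefDetection],
    curr_unknown: Sequence[RefDetection],
    shift: np.ndarray,
    radius: Optional[float] = None,
    exclude_ids: Iterable[int] = (),
) -> list[RefDetection]:
    """Recover lost identities by projecting last frame's cubes forward.

    Each previously identified centroid, moved by the image shift, is
    matched to the nearest unknown box centroid within ``radius`` (default:
    the projected box diagonal, per detection — wide enough to absorb the
    radial residuals that a translation-only shift leaves under zooming,
    while still far smaller than the spacing between cubes).  Assignment
    is greedy
    nearest-first and one-to-one; identities in ``exclude_ids`` (already
    present in the current frame) are never re-assigned.  Recovered
    detections are flagged with ``provenance="recovered"``.
    """
    shift = np.asarray(shift, dtype=float)
    exclude = set(exclude_ids)
    candidates = []
    for pi, p in enumerate(prev):
        if p.ref_id is None or p.ref_id in exclude:
            continue
        proj = p.centroid + shift
        r = (
            radius
            if radius is not None
            else float(np.hypot(p.box[2] - p.box[0], p.box[3] - p.box[1]))
        )
        for ci, c in enumerate(curr_unknown):
            d = float(np.linalg.norm(c.centroid - proj))
            if d <= r:
                candidates.append((d, pi, ci))
    candidates.sort(key=lambda t: t[0])
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    out = [c.copy() for c in curr_unknown]
    for d, pi, ci in candidates:
        if pi in used_prev or ci in used_curr:
            continue
        used_prev.add(pi)
        used_curr.add(ci)
        out[ci].ref_id = prev[pi].ref_id
        out[ci].provenance = "recovered"
    return out


def identify_stream(
    frames: dict[int, list[RefDetection]],
    overlap_threshold: float = 0.5,
    recovery_radius: Optional[float] = None,
) -> dict[int, list[RefDetection]]:
    """Run the full per-camera association chain over an ordered frame range.

    Per frame: discard overlaps, keep direct identifications, then recover
    identities of the previous frame's cubes among the still-unknown boxes
    using the median shift vector.  The previous frame's *processed* result
    (direct plus recovered) seeds the next frame, so an identity can ride
    through several unidentified frames.  Guarantees that no ref_id appears
    twice within one frame.
    """
    result: dict[int, list[RefDetection]] = {}
    prev: list[RefDetection] = []
    for f in sorted(frames):
        dets = discard_overlaps(frames[f], overlap_threshold)
        identified = [d.copy() for d in dets if d.ref_id is not None]
        # defensive de-duplication: keep the most confident of any repeated id
        seen: dict[int, RefDetection] = {}
        for d in identified:
            if d.ref_id not in seen or d.confidence > seen[d.ref_id].confidence:
                seen[d.ref_id] = d
        identified = list(seen.values())
        unknown = [d for d in dets if d.ref_id is None]

        recovered: list[RefDetection] = []
        if prev and unknown:
            shift = estimate_shift(prev, identified)
            if shift is not None:
                rec = temporal_recover(
                    prev,
                    unknown,
                    shift,
                    radius=recovery_radius,
                    exclude_ids=[d.ref_id for d in identified],
                )
                recovered = [d for d in rec if d.ref_id is not None]
        n_rec = len(recovered)
        if n_rec:
            logger.debug("frame %d: recovered %d identities", f, n_rec)
        result[f] = identified + recovered
        prev = result[f]
    total = sum(len(v) for v in result.values())
    n_recovered = sum(
        1 for v in result.values() for d in v if d.provenance == "recovered"
    )
    logger.info(
        "identified %d cube observations (%d via temporal recovery)",
        total,
        n_recovered,
    )
    return result
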