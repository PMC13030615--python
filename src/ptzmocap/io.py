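"""On-disk formats: plain text, versioned, diffable.

Surveyed points travel as CSV (``ref_id,x,y,z``); detection streams as
JSON-lines with one record per camera-frame; ground truth, projection
matrices, sync results and reports as JSON; configuration as YAML.  Every
format carries a version field so readers can refuse what they do not
understand.  Missing values (undetected keypoints) are encoded as JSON
null, never as sentinel numbers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    CameraStream,
    ConfigurationError,
    DropTrack,
    GroundTruth,
    Pose3D,
    PoseObservation,
    ProjectionMatrix,
    RefDetection,
    SceneConfig,
    SurveyedPoint,
    SyncResult,
)

FORMAT_VERSION = "1"

__all__ = [
    "FORMAT_VERSION",
    "read_surveyed_points",
    "write_surveyed_points",
    "read_detections",
    "write_detections",
    "read_drop_tracks",
    "write_drop_tracks",
    "read_ground_truth",
    "write_ground_truth",
    "read_matrices",
    "write_matrices",
    "read_sync_result",
    "write_sync_result",
    "export_trajectories",
    "import_trajectories",
    "read_config",
    "write_config",
]


class FormatError(ConfigurationError):
    """A file does not conform to its declared schema."""


# ---------------------------------------------------------------------- CSV

def write_surveyed_points(points: Sequence[SurveyedPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ref_id", "x", "y", "z"])
        for p in points:
            w.writerow([p.ref_id] + [repr(float(v)) for v in p.position])


def read_surveyed_points(path: str | Path) -> list[SurveyedPoint]:
    """Read the survey table, rejecting malformed rows and duplicate ids."""
    points = []
    seen: set[int] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["ref_id", "x", "y", "z"]:
            raise FormatError(f"{path}: expected header 'ref_id,x,y,z'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rid = int(row[0])
                pos = np.array([float(row[1]), float(row[2]), float(row[3])])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}") from exc
            if rid in seen:
                raise FormatError(f"{path}: duplicate ref_id {rid} at line {lineno}")
            seen.add(rid)
            points.append(SurveyedPoint(ref_id=rid, position=pos))
    return points


# --------------------------------------------------------------- JSON-lines

def _ref_to_json(d: RefDetection) -> dict:
    return {
        "box": [float(v) for v in d.box],
        "centroid": [float(v) for v in d.centroid],
        "confidence": float(d.confidence),
        "ref_id": d.ref_id,
        "provenance": d.provenance,
    }


def _pose_to_json(p: PoseObservation) -> dict:
    kps = [
        None if np.any(np.isnan(kp)) else [float(kp[0]), float(kp[1])]
        for kp in p.keypoints
    ]
    return {"keypoints": kps, "confidence": [float(c) for c in p.confidence]}


def write_detections(streams: dict[str, CameraStream], path: str | Path) -> None:
    """One JSON record per camera-frame, cameras then frames in order."""
    with open(path, "w") as fh:
        for cid in sorted(streams):
            s = streams[cid]
            frames = sorted(set(s.refs) | set(s.poses) | set(s.skier_centroid))
            for f in frames:
                rec = {
                    "version": FORMAT_VERSION,
                    "camera": cid,
                    "frame": f,
                    "refs": [_ref_to_json(d) for d in s.refs.get(f, [])],
                }
                if f in s.poses:
                    rec["pose"] = _pose_to_json(s.poses[f])
                if f in s.skier_centroid:
                    rec["skier_centroid"] = [float(v) for v in s.skier_centroid[f]]
                fh.write(json.dumps(rec) + "\n")


def read_detections(path: str | Path) -> dict[str, CameraStream]:
    streams: dict[str, CameraStream] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if rec.get("version") != FORMAT_VERSION:
                raise FormatError(
                    f"{path}: record {i}: unknown schema version {rec.get('version')!r}"
                )
            try:
                cid, f = rec["camera"], int(rec["frame"])
                refs = rec["refs"]
            except KeyError as exc:
                raise FormatError(f"{path}: record {i}: missing field {exc}") from exc
            s = streams.setdefault(cid, CameraStream(camera_id=cid))
            s.refs[f] = [
                RefDetection(
                    camera_id=cid,
                    frame=f,
                    box=np.array(r["box"]),
                    centroid=np.array(r["centroid"]),
                    confidence=r["confidence"],
                    ref_id=r["ref_id"],
                    provenance=r.get("provenance", "direct"),
                )
                for r in refs
            ]
            if "pose" in rec:
                kps = np.array(
                    [
                        [np.nan, np.nan] if kp is None else kp
                        for kp in rec["pose"]["keypoints"]
                    ],
                    dtype=float,
                )
                s.poses[f] = PoseObservation(
                    camera_id=cid,
                    frame=f,
                    keypoints=kps,
                    confidence=np.array(rec["pose"]["confidence"], dtype=float),
                )
            if "skier_centroid" in rec:
                s.skier_centroid[f] = np.array(rec["skier_centroid"], dtype=float)
    return streams


# --------------------------------------------------------------------- JSON

def write_drop_tracks(tracks: dict[str, DropTrack], path: str | Path) -> None:
    payload = {
        "version": FORMAT_VERSION,
        "tracks": {
            cid: {"frames": t.frames.tolist(), "y": t.y.tolist()}
            for cid, t in tracks.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_drop_tracks(path: str | Path) -> dict[str, DropTrack]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unknown schema version")
    return {
        cid: DropTrack(camera_id=cid, frames=np.array(t["frames"]), y=np.array(t["y"]))
        for cid, t in payload["tracks"].items()
    }


def write_sync_result(sync: SyncResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "version": FORMAT_VERSION,
                "reference": sync.reference,
                "events": sync.events,
                "offsets": sync.offsets,
            },
            indent=1,
        )
    )


def read_sync_result(path: str | Path) -> SyncResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unknown schema version")
    return SyncResult(
        reference=payload["reference"],
        events=payload["events"],
        offsets=payload["offsets"],
    )


def write_matrices(
    matrices: dict[str, dict[int, ProjectionMatrix]], path: str | Path
) -> None:
    payload = {
        "version": FORMAT_VERSION,
        "matrices": {
            cid: {str(f): pm.P.tolist() for f, pm in per_frame.items()}
            for cid, per_frame in matrices.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_matrices(path: str | Path) -> dict[str, dict[int, ProjectionMatrix]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unknown schema version")
    return {
        cid: {
            int(f): ProjectionMatrix(P=np.array(P), camera_id=cid, frame=int(f))
            for f, P in per_frame.items()
        }
        for cid, per_frame in payload["matrices"].items()
    }


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "version": FORMAT_VERSION,
        "keypoints3d": truth.keypoints3d.tolist(),
        "centroid3d": truth.centroid3d.tolist(),
        "projections": {c: p.tolist() for c, p in truth.projections.items()},
        "offsets": truth.offsets,
        "segment_lengths": truth.segment_lengths,
        "refpoint_positions": {
            str(rid): pos.tolist() for rid, pos in truth.refpoint_positions.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != FORMAT_VERSION:
        raise FormatError(f"{path}: unknown schema version")
    return GroundTruth(
        keypoints3d=np.array(payload["keypoints3d"]),
        centroid3d=np.array(payload["centroid3d"]),
        projections={c: np.array(p) for c, p in payload["projections"].items()},
        offsets=payload["offsets"],
        segment_lengths=payload["segment_lengths"],
        refpoint_positions={
            int(r): np.array(p) for r, p in payload["refpoint_positions"].items()
        },
    )


# ------------------------------------------------------------- trajectories

def export_trajectories(
    poses: Sequence[Pose3D],
    path: str | Path,
    keypoint_names: Sequence[str],
    fmt: str = "csv",
) -> None:
    """Long-form trajectory export: frame, keypoint, x, y, z, n_views.

    Missing keypoints are omitted (absent rows), never written as zeros.
    """
    rows = []
    for p in poses:
        for k, name in enumerate(keypoint_names):
            if np.any(np.isnan(p.points[k])):
                continue
            rows.append(
                {
                    "frame": p.frame,
                    "keypoint": name,
                    "x": p.points[k, 0],
                    "y": p.points[k, 1],
                    "z": p.points[k, 2],
                    "n_views": int(p.n_views[k]),
                }
            )
    df = pd.DataFrame(
        rows, columns=["frame", "keypoint", "x", "y", "z", "n_views"]
    )
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        Path(path).write_text(
            json.dumps({"version": FORMAT_VERSION, "rows": rows}, default=float)
        )
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")


def import_trajectories(
    path: str | Path, keypoint_names: Sequence[str], fmt: str = "csv"
) -> list[Pose3D]:
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "json":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != FORMAT_VERSION:
            raise FormatError(f"{path}: unknown schema version")
        df = pd.DataFrame(
            payload["rows"], columns=["frame", "keypoint", "x", "y", "z", "n_views"]
        )
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")
    idx = {n: i for i, n in enumerate(keypoint_names)}
    poses = []
    if df.empty:
        return poses
    for frame, grp in df.groupby("frame", sort=True):
        pts = np.full((len(keypoint_names), 3), np.nan)
        n_views = np.zeros(len(keypoint_names), dtype=int)
        for _, row in grp.iterrows():
            k = idx[row["keypoint"]]
            pts[k] = [row["x"], row["y"], row["z"]]
            n_views[k] = int(row["n_views"])
        poses.append(Pose3D(frame=int(frame), points=pts, n_views=n_views))
    return poses


# ------------------------------------------------------------------- config

def write_config(config: SceneConfig, path: str | Path) -> None:
    payload = {"version": FORMAT_VERSION, **dataclasses.asdict(config)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config(path: str | Path) -> SceneConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if str(payload.pop("version", None)) != FORMAT_VERSION:
        raise FormatError(f"{path}: unknown config version")
    fields = {f.name for f in dataclasses.fields(SceneConfig)}
    unknown = set(payload) - fields
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("corridor_extent", "image_size", "frame_offsets"):
        if payload.get(key) is not None:
            payload[key] = tuple(payload[key])
    cfg = SceneConfig(**payload)
    cfg.validate()
    return cfg
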