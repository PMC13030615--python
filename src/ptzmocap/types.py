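"""Shared domain types for the motion-capture pipeline.

Conventions used throughout the package (stated once, used everywhere):

* image frame: origin top-left, x right, y down, units pixels;
* world frame: x downhill, y across the slope, z up, units metres;
* camera frames are indexed by integers; camera ``c``'s frame ``f`` is
  exposed at absolute time ``(f + delta_c) / frame_rate`` where ``delta_c``
  is that camera's fractional frame offset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SceneConfig",
    "SurveyedPoint",
    "CameraTrack",
    "SkeletonModel",
    "RefDetection",
    "PoseObservation",
    "Pose3D",
    "DropTrack",
    "SyncResult",
    "ProjectionMatrix",
    "Correspondence",
    "FrameCalibration",
    "CalibrationReport",
    "SubsetChoice",
    "CameraStream",
    "GroundTruth",
    "TrialBundle",
    "ConfigurationError",
    "NoEventError",
    "DegenerateGeometryError",
    "InsufficientDataError",
]


class ConfigurationError(ValueError):
    """Invalid scene or pipeline configuration."""


class NoEventError(RuntimeError):
    """No synchronization event (fall followed by bounce) could be found."""


class DegenerateGeometryError(RuntimeError):
    """Point configuration does not determine a unique projection matrix."""


class InsufficientDataError(RuntimeError):
    """Fewer observations than the operation requires."""


@dataclass
class SceneConfig:
    """Parameters of a synthetic downhill trial.

    Defaults emulate the field setup at reduced scale: a sloped corridor
    watched by a ring of pan-tilt-zoom cameras, surveyed reference cubes
    scattered over the corridor on poles of varying height, and a skier
    carving down the fall line at racing speed.
    """

    n_cameras: int = 4
    n_refpoints: int = 80
    #: corridor length (downhill), width (across), height band of the slope [m]
    corridor_extent: tuple[float, float, float] = (60.0, 20.0, 10.0)
    slope_angle: float = 15.0  # degrees
    frame_rate: float = 25.0  # Hz
    n_frames: int = 100
    pixel_noise_sd: float = 0.5  # detector localisation noise on cube centroids [px]
    ref_dropout_prob: float = 0.05  # chance a visible cube is not localised
    id_dropout_prob: float = 0.10  # chance a localised cube is not identified
    keypoint_noise_sd: float = 2.0  # keypoint detector noise [px]
    #: per-camera fractional frame offsets; None means all zero
    frame_offsets: Optional[tuple[float, ...]] = None
    ref_drift: float = 0.0  # max displacement of cubes after surveying [m]
    rng_seed: int = 0

    # motion / camera shaping parameters
    skier_speed: float = 15.0  # along-slope speed [m/s], typical for carving
    turn_period: float = 3.0  # seconds per full left-right turn cycle
    turn_amplitude: float = 3.0  # lateral half-width of the turns [m]
    camera_distance: float = 28.0  # lateral stand-off of cameras from corridor edge [m]
    aim_lag: float = 0.0  # camera operator lag when tracking the skier [s]
    pixels_per_metre: float = 200.0  # zoom target: apparent scale at the skier
    image_size: tuple[int, int] = (3840, 2160)
    cube_size: float = 0.09  # edge length of the reference cubes [m]

    def validate(self) -> None:
        if self.n_cameras < 2:
            raise ConfigurationError("at least two cameras are required")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.n_refpoints < 6:
            raise ConfigurationError("need at least six reference points")
        for name in ("ref_dropout_prob", "id_dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("pixel_noise_sd", "keypoint_noise_sd", "ref_drift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.frame_offsets is not None and len(self.frame_offsets) != self.n_cameras:
            raise ConfigurationError("frame_offsets must have one entry per camera")

    def offsets(self) -> np.ndarray:
        if self.frame_offsets is None:
            return np.zeros(self.n_cameras)
        return np.asarray(self.frame_offsets, dtype=float)


@dataclass(frozen=True)
class SurveyedPoint:
    """A geodetically surveyed reference cube: identity plus world position."""

    ref_id: int
    position: np.ndarray  # (3,) metres

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ConfigurationError(f"bad surveyed position for ref {self.ref_id}")


@dataclass
class CameraTrack:
    """Time-varying pinhole camera: fixed centre, per-frame rotation and zoom."""

    camera_id: str
    position: np.ndarray  # (3,) metres, fixed
    rotations: np.ndarray  # (n_frames, 3, 3), world -> camera
    focal: np.ndarray  # (n_frames,) pixels
    principal_point: np.ndarray  # (2,) pixels
    image_size: tuple[int, int] = (3840, 2160)

    def projection(self, frame: int) -> np.ndarray:
        """3x4 projection matrix P = K [R | -R C] for one frame."""
        f = self.focal[frame]
        cx, cy = self.principal_point
        K = np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])
        R = self.rotations[frame]
        Rt = np.hstack([R, -R @ self.position[:, None]])
        return K @ Rt


@dataclass
class SkeletonModel:
    """Keypoint schema and the rigid segments measured for evaluation."""

    keypoint_names: tuple[str, ...]
    #: segment name -> (proximal keypoint, distal keypoint)
    segments: dict[str, tuple[str, str]]
    #: segment name -> length in metres (constant in ground truth)
    segment_lengths: dict[str, float]

    def __post_init__(self) -> None:
        names = set(self.keypoint_names)
        for seg, (a, b) in self.segments.items():
            if a not in names or b not in names:
                raise ConfigurationError(f"segment {seg} references unknown keypoint")

    def index(self, name: str) -> int:
        return self.keypoint_names.index(name)

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoint_names)


@dataclass
class RefDetection:
    """One per-frame observation of a reference cube in one camera."""

    camera_id: str
    frame: int
    box: np.ndarray  # (4,) x_min, y_min, x_max, y_max [px]
    centroid: np.ndarray  # (2,) box centre [px]
    confidence: float = 1.0
    ref_id: Optional[int] = None
    provenance: str = "direct"  # "direct" | "recovered" | "interpolated"

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not (self.box[0] < self.box[2] and self.box[1] < self.box[3]):
            raise ConfigurationError("degenerate bounding box")

    def copy(self) -> "RefDetection":
        return dataclasses.replace(
            self, box=self.box.copy(), centroid=self.centroid.copy()
        )


@dataclass
class PoseObservation:
    """Per-frame 2D keypoints of the skier in one camera (NaN = missing)."""

    camera_id: str
    frame: int
    keypoints: np.ndarray  # (K, 2) pixels, NaN where undetected
    confidence: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)


@dataclass
class Pose3D:
    """Reconstructed 3D keypoints for one frame (NaN = not reconstructed)."""

    frame: int
    points: np.ndarray  # (K, 3) metres
    n_views: np.ndarray  # (K,) contributing cameras, 0 where missing


@dataclass
class DropTrack:
    """Vertical pixel trace of the dropped synchronization cube in one camera."""

    camera_id: str
    frames: np.ndarray  # (n,) strictly increasing integer frame indices
    y: np.ndarray  # (n,) vertical pixel coordinate

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) != len(self.y):
            raise ConfigurationError("frames and y must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ConfigurationError("frame indices must be strictly increasing")


@dataclass
class SyncResult:
    """Per-camera sub-frame event times and offsets relative to a reference."""

    reference: str
    events: dict[str, float]  # camera -> event time [frames]
    offsets: dict[str, float]  # camera -> offset relative to reference [frames]


@dataclass
class ProjectionMatrix:
    """3x4 world-to-image mapping for one camera at one frame."""

    P: np.ndarray
    camera_id: str = ""
    frame: int = -1

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (3, 4):
            raise ConfigurationError("projection matrix must be 3x4")

    def project(self, world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points (3,) or (n, 3) -> pixel coords and depths."""
        pts = np.asarray(world, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        h = (self.P @ np.hstack([pts2, np.ones((len(pts2), 1))]).T).T
        uv = h[:, :2] / h[:, 2:3]
        depth = h[:, 2]
        if single:
            return uv[0], float(depth[0])
        return uv, depth


@dataclass(frozen=True)
class Correspondence:
    """A surveyed 3D position paired with its image observation."""

    ref_id: int
    world: np.ndarray  # (3,) metres
    image: np.ndarray  # (2,) pixels

    def __post_init__(self) -> None:
        object.__setattr__(self, "world", np.asarray(self.world, dtype=float))
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))


@dataclass
class FrameCalibration:
    """Outcome of calibrating one camera at one frame."""

    status: str  # "calibrated" | "excluded" | "degenerate"
    used_ids: tuple[int, ...] = ()
    rejected_ids: tuple[int, ...] = ()
    mean_error: float = float("nan")  # mean reprojection error of used points [px]


@dataclass
class CalibrationReport:
    """Per-camera, per-frame calibration bookkeeping for a trial."""

    frames: dict[str, dict[int, FrameCalibration]] = field(default_factory=dict)

    def n_calibrated(self, camera_id: str) -> int:
        return sum(
            1 for fc in self.frames.get(camera_id, {}).values() if fc.status == "calibrated"
        )

    def n_excluded(self, camera_id: str) -> int:
        return sum(
            1 for fc in self.frames.get(camera_id, {}).values() if fc.status != "calibrated"
        )

    def rejected_counts(self) -> dict[int, int]:
        """How often each ref_id was rejected as an outlier, over all frames."""
        counts: dict[int, int] = {}
        for per_frame in self.frames.values():
            for fc in per_frame.values():
                for rid in fc.rejected_ids:
                    counts[rid] = counts.get(rid, 0) + 1
        return counts


@dataclass
class SubsetChoice:
    """The fixed camera subset used for a whole trial, with its score."""

    cameras: tuple[str, ...]
    mean_error: float  # mean reprojection error into the subset's views [px]


@dataclass
class CameraStream:
    """Everything one camera observed during a trial."""

    camera_id: str
    #: frame -> reference-cube detections
    refs: dict[int, list[RefDetection]] = field(default_factory=dict)
    #: frame -> skier keypoints
    poses: dict[int, PoseObservation] = field(default_factory=dict)
    #: frame -> approximate skier image position (person-box centroid)
    skier_centroid: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Known truth of a synthetic trial, on the reference (offset-0) timeline."""

    keypoints3d: np.ndarray  # (n_frames, K, 3) metres
    centroid3d: np.ndarray  # (n_frames, 3) metres
    projections: dict[str, np.ndarray]  # camera -> (n_frames, 3, 4), at own sample times
    offsets: dict[str, float]  # camera -> true fractional frame offset
    segment_lengths: dict[str, float]
    #: cube positions actually rendered (equal to the surveyed table unless drifted)
    refpoint_positions: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class TrialBundle:
    """All synchronized inputs for one run: detections, survey table, schema."""

    config: SceneConfig
    surveyed: list[SurveyedPoint]
    streams: dict[str, CameraStream]
    skeleton: SkeletonModel

    @property
    def frame_rate(self) -> float:
        return self.config.frame_rate

    def surveyed_table(self) -> dict[int, np.ndarray]:
        return {p.ref_id: p.position for p in self.surveyed}
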