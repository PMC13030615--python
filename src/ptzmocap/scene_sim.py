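"""Synthetic outdoor capture scenes with known ground truth.

Emulates the field protocol entirely in software: a sloped corridor with
surveyed reference cubes on poles, an articulated skier descending in
sinusoidal turns at carving speed, and a ring of pan-tilt-zoom pinhole
cameras that track the skier.  The renderer produces the same detection
streams a real localisation/identification front end would: reference-cube
bounding boxes (with identification dropout), skier keypoints with
confidences, and drop-cube traces for sub-frame synchronization — all with
seeded noise, so every downstream stage can be tested against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (
    CameraStream,
    CameraTrack,
    ConfigurationError,
    DropTrack,
    GroundTruth,
    PoseObservation,
    RefDetection,
    SceneConfig,
    SkeletonModel,
    SurveyedPoint,
    TrialBundle,
)

__all__ = [
    "HALPE26_KEYPOINTS",
    "SKI_KEYPOINTS",
    "SEGMENT_DEFINITIONS",
    "default_skeleton",
    "generate_scene",
    "render_drop_event",
    "perturb_refpoints",
    "DropTruth",
]

GRAVITY = 9.81  # m/s^2

#: 26-keypoint whole-body convention (head/trunk/limbs plus toes and heels).
HALPE26_KEYPOINTS = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
    "head", "neck", "hip",
    "left_big_toe", "right_big_toe", "left_small_toe", "right_small_toe",
    "left_heel", "right_heel",
)

#: Skier-specific additions: ski tips/tails and pole tips, per side.
SKI_KEYPOINTS = (
    "left_ski_tip", "right_ski_tip",
    "left_ski_tail", "right_ski_tail",
    "left_pole_tip", "right_pole_tip",
)

#: The eight rigid segments whose length variation scores reconstruction.
SEGMENT_DEFINITIONS = {
    "upper_arm_left": ("left_shoulder", "left_elbow"),
    "upper_arm_right": ("right_shoulder", "right_elbow"),
    "forearm_left": ("left_elbow", "left_wrist"),
    "forearm_right": ("right_elbow", "right_wrist"),
    "thigh_left": ("left_hip", "left_knee"),
    "thigh_right": ("right_hip", "right_knee"),
    "shank_left": ("left_knee", "left_ankle"),
    "shank_right": ("right_knee", "right_ankle"),
}

_DEFAULT_LENGTHS = {
    "upper_arm_left": 0.30, "upper_arm_right": 0.30,
    "forearm_left": 0.26, "forearm_right": 0.26,
    "thigh_left": 0.42, "thigh_right": 0.42,
    "shank_left": 0.43, "shank_right": 0.43,
}


def default_skeleton() -> SkeletonModel:
    """HALPE26 plus six ski/pole keypoints, adult segment lengths."""
    return SkeletonModel(
        keypoint_names=HALPE26_KEYPOINTS + SKI_KEYPOINTS,
        segments=dict(SEGMENT_DEFINITIONS),
        segment_lengths=dict(_DEFAULT_LENGTHS),
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class _SkierMotion:
    """Continuous-time articulated skier: constant-speed descent with
    sinusoidal turns, limb directions oscillating at the turn cadence.

    All eight measured segments are built as ``parent + length * unit(dir)``
    so their lengths are constant to machine precision at every time.
    """

    def __init__(self, config: SceneConfig, skeleton: SkeletonModel):
        self.cfg = config
        self.skeleton = skeleton
        self.beta = math.radians(config.slope_angle)
        self.vx = config.skier_speed * math.cos(self.beta)
        self.omega = 2.0 * math.pi / config.turn_period
        self.z0 = config.corridor_extent[2]
        self.lengths = skeleton.segment_lengths
        self.idx = {n: i for i, n in enumerate(skeleton.keypoint_names)}

    def surface_z(self, x: float) -> float:
        return self.z0 - x * math.tan(self.beta)

    def centroid(self, t: float) -> np.ndarray:
        """Pelvis position: the skier's body centre on its descending path."""
        x = self.vx * t
        y = self.cfg.turn_amplitude * math.sin(self.omega * t)
        z = self.surface_z(x) + 0.95
        return np.array([x, y, z])

    def _frame_axes(self, t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        vel = np.array(
            [
                self.vx,
                self.cfg.turn_amplitude * self.omega * math.cos(self.omega * t),
                -self.vx * math.tan(self.beta),
            ]
        )
        fwd = _unit(vel)
        side = _unit(np.cross(fwd, np.array([0.0, 0.0, 1.0])))
        up = np.cross(side, fwd)
        return fwd, side, up

    def keypoints(self, t: float) -> np.ndarray:
        """All keypoint world positions at continuous time t (K, 3)."""
        cfg, L = self.cfg, self.lengths
        pelvis = self.centroid(t)
        fwd, side, up = self._frame_axes(t)
        w = self.omega
        pts = np.zeros((self.skeleton.n_keypoints, 3))

        def put(name: str, pos: np.ndarray) -> np.ndarray:
            pts[self.idx[name]] = pos
            return pos

        hip_c = put("hip", pelvis)
        neck = put("neck", pelvis + 0.50 * up + 0.05 * fwd)
        head = put("head", neck + 0.18 * up)
        put("nose", head + 0.08 * fwd - 0.03 * up)
        put("left_eye", head + 0.07 * fwd + 0.03 * side)
        put("right_eye", head + 0.07 * fwd - 0.03 * side)
        put("left_ear", head + 0.01 * fwd + 0.07 * side)
        put("right_ear", head + 0.01 * fwd - 0.07 * side)

        for sgn, pre in ((1.0, "left"), (-1.0, "right")):
            hip = put(f"{pre}_hip", hip_c + 0.11 * sgn * side)
            sh = put(f"{pre}_shoulder", neck + 0.19 * sgn * side)

            # legs: flexed skiing stance, flexion oscillating with the turns
            th = 0.55 + 0.22 * math.sin(w * t + (0.0 if sgn > 0 else math.pi / 3))
            thigh_dir = _unit(-math.cos(th) * up + math.sin(th) * fwd)
            knee = put(f"{pre}_knee", hip + L[f"thigh_{pre}"] * thigh_dir)
            sk = th - 0.95 - 0.15 * math.sin(w * t + sgn * 0.7)
            shank_dir = _unit(-math.cos(sk) * up + math.sin(sk) * fwd)
            ankle = put(f"{pre}_ankle", knee + L[f"shank_{pre}"] * shank_dir)

            # arms: held forward-down, swinging slightly
            ua = 0.5 + 0.25 * math.sin(w * t + sgn * 1.2)
            uarm_dir = _unit(-math.cos(ua) * up + 0.35 * sgn * side + math.sin(ua) * fwd)
            elbow = put(f"{pre}_elbow", sh + L[f"upper_arm_{pre}"] * uarm_dir)
            fa = ua + 0.8 + 0.1 * math.cos(w * t)
            farm_dir = _unit(-math.cos(fa) * up + 0.15 * sgn * side + math.sin(fa) * fwd)
            wrist = put(f"{pre}_wrist", elbow + L[f"forearm_{pre}"] * farm_dir)

            # feet and skis ride with the ankle
            put(f"{pre}_big_toe", ankle + 0.18 * fwd - 0.08 * up + 0.02 * sgn * side)
            put(f"{pre}_small_toe", ankle + 0.16 * fwd - 0.08 * up + 0.06 * sgn * side)
            put(f"{pre}_heel", ankle - 0.08 * fwd - 0.09 * up)
            put(f"{pre}_ski_tip", ankle + 0.95 * fwd - 0.10 * up)
            put(f"{pre}_ski_tail", ankle - 0.70 * fwd - 0.10 * up)
            put(f"{pre}_pole_tip", wrist - 1.05 * up + 0.30 * sgn * side - 0.25 * fwd)

        return pts


def _scatter_refpoints(
    config: SceneConfig, motion: _SkierMotion, rng: np.random.Generator
) -> list[SurveyedPoint]:
    """Cubes on poles of varying height, scattered over the corridor but
    clear of the skier's line; heights vary so the field is non-coplanar."""
    L, W, _ = config.corridor_extent
    points = []
    for rid in range(config.n_refpoints):
        while True:
            x = rng.uniform(-0.05 * L, 1.05 * L)
            y = rng.uniform(-W / 2, W / 2)
            if abs(y) > config.turn_amplitude + 1.0:
                break
        z = motion.surface_z(x) + rng.uniform(0.5, 1.5)
        points.append(SurveyedPoint(ref_id=rid, position=np.array([x, y, z])))
    return points


def _look_at(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation: optical axis to target, image y pointing down."""
    fwd = _unit(target - position)
    right = np.cross(fwd, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(right) < 1e-12:  # looking straight up/down
        right = np.array([1.0, 0.0, 0.0])
    right = _unit(right)
    down = np.cross(fwd, right)
    return np.stack([right, down, fwd])


def _camera_positions(config: SceneConfig, motion: _SkierMotion) -> list[np.ndarray]:
    L, W, _ = config.corridor_extent
    positions = []
    for i in range(config.n_cameras):
        side = 1.0 if i % 2 == 0 else -1.0
        x = L * (i + 0.5) / config.n_cameras
        y = side * (W / 2 + config.camera_distance)
        z = motion.surface_z(x) + 6.0
        positions.append(np.array([x, y, z]))
    return positions


def _build_camera_tracks(
    config: SceneConfig, motion: _SkierMotion
) -> dict[str, CameraTrack]:
    """PTZ emulation: each camera pans/tilts to follow the skier centroid
    (with optional operator lag) and zooms so the skier's apparent scale
    stays roughly constant."""
    offsets = config.offsets()
    cams: dict[str, CameraTrack] = {}
    w_img, h_img = config.image_size
    pp = np.array([w_img / 2.0, h_img / 2.0])
    for i, pos in enumerate(_camera_positions(config, motion)):
        cid = f"cam{chr(ord('A') + i)}"
        rots = np.zeros((config.n_frames, 3, 3))
        focal = np.zeros(config.n_frames)
        for f in range(config.n_frames):
            t = (f + offsets[i]) / config.frame_rate
            target = motion.centroid(max(t - config.aim_lag, 0.0))
            rots[f] = _look_at(pos, target)
            focal[f] = config.pixels_per_metre * np.linalg.norm(target - pos)
        cams[cid] = CameraTrack(
            camera_id=cid,
            position=pos,
            rotations=rots,
            focal=focal,
            principal_point=pp,
            image_size=config.image_size,
        )
    return cams


def _project(P: np.ndarray, world: np.ndarray) -> tuple[np.ndarray, float]:
    h = P @ np.append(world, 1.0)
    return h[:2] / h[2], h[2]


def perturb_refpoints(
    points: list[SurveyedPoint], drift: float, seed: int | np.random.Generator = 0
) -> list[SurveyedPoint]:
    """Displace each cube by a random vector of magnitude <= drift metres.

    Emulates heat- and traffic-induced pole movement between surveying and
    recording (observed in the field at up to 0.16 m).
    """
    if drift < 0:
        raise ConfigurationError("drift must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if drift == 0:
        return [SurveyedPoint(p.ref_id, p.position.copy()) for p in points]
    out = []
    for p in points:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        magnitude = rng.uniform(0.0, drift)
        out.append(SurveyedPoint(p.ref_id, p.position + magnitude * direction))
    return out


def generate_scene(config: SceneConfig) -> tuple[TrialBundle, GroundTruth]:
    """Render a full synthetic trial and its exact ground truth.

    Every stochastic draw (cube placement, noise, dropout, drift) comes from
    ``config.rng_seed``, so identical configs give bit-identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    skeleton = default_skeleton()
    motion = _SkierMotion(config, skeleton)

    surveyed = _scatter_refpoints(config, motion, rng)
    rendered = perturb_refpoints(surveyed, config.ref_drift, rng)
    cams = _build_camera_tracks(config, motion)
    offsets = config.offsets()
    w_img, h_img = config.image_size

    n_kp = skeleton.n_keypoints
    gt_kp = np.zeros((config.n_frames, n_kp, 3))
    gt_centroid = np.zeros((config.n_frames, 3))
    for f in range(config.n_frames):
        t = f / config.frame_rate
        gt_kp[f] = motion.keypoints(t)
        gt_centroid[f] = motion.centroid(t)

    streams: dict[str, CameraStream] = {}
    gt_proj: dict[str, np.ndarray] = {}
    gt_offsets: dict[str, float] = {}

    for i, (cid, cam) in enumerate(cams.items()):
        stream = CameraStream(camera_id=cid)
        proj = np.zeros((config.n_frames, 3, 4))
        for f in range(config.n_frames):
            t = (f + offsets[i]) / config.frame_rate
            P = cam.projection(f)
            proj[f] = P

            # --- reference cubes ---
            dets: list[RefDetection] = []
            for p in rendered:
                uv, depth = _project(P, p.position)
                if depth <= 0:
                    continue
                half = 0.5 * cam.focal[f] * config.cube_size / depth
                if not (
                    half <= uv[0] <= w_img - half and half <= uv[1] <= h_img - half
                ):
                    continue
                if rng.random() < config.ref_dropout_prob:
                    continue
                noise = (
                    rng.normal(0.0, config.pixel_noise_sd, size=2)
                    if config.pixel_noise_sd > 0
                    else np.zeros(2)
                )
                c = uv + noise
                identified = rng.random() >= config.id_dropout_prob
                dets.append(
                    RefDetection(
                        camera_id=cid,
                        frame=f,
                        box=np.array([c[0] - half, c[1] - half, c[0] + half, c[1] + half]),
                        centroid=c,
                        confidence=float(rng.uniform(0.8, 1.0)),
                        ref_id=p.ref_id if identified else None,
                    )
                )
            stream.refs[f] = dets

            # --- skier keypoints ---
            kp_world = motion.keypoints(t)
            kp_px = np.full((n_kp, 2), np.nan)
            conf = np.zeros(n_kp)
            for k in range(n_kp):
                uv, depth = _project(P, kp_world[k])
                if depth <= 0 or not (0 <= uv[0] < w_img and 0 <= uv[1] < h_img):
                    continue
                if config.keypoint_noise_sd > 0:
                    uv = uv + rng.normal(0.0, config.keypoint_noise_sd, size=2)
                kp_px[k] = uv
                conf[k] = float(rng.uniform(0.85, 1.0))
            stream.poses[f] = PoseObservation(
                camera_id=cid, frame=f, keypoints=kp_px, confidence=conf
            )

            c_uv, c_depth = _project(P, motion.centroid(t))
            if c_depth > 0:
                stream.skier_centroid[f] = c_uv
        streams[cid] = stream
        gt_proj[cid] = proj
        gt_offsets[cid] = float(offsets[i])

    bundle = TrialBundle(
        config=config, surveyed=surveyed, streams=streams, skeleton=skeleton
    )
    truth = GroundTruth(
        keypoints3d=gt_kp,
        centroid3d=gt_centroid,
        projections=gt_proj,
        offsets=gt_offsets,
        segment_lengths=dict(skeleton.segment_lengths),
        refpoint_positions={p.ref_id: p.position for p in rendered},
    )
    return bundle, truth


@dataclass
class DropTruth:
    """Exact event times of a rendered drop, for validating synchronization."""

    impact_time: float  # seconds
    events: dict[str, float]  # camera -> event time in that camera's frames
    offsets: dict[str, float]  # camera -> offset vs lexicographic reference [frames]


def render_drop_event(
    config: SceneConfig,
    drop_height: float = 2.0,
    restitution: float = 0.55,
    rest_frames: int = 8,
    camera_distance: float = 20.0,
    pixels_per_metre: float = 400.0,
    noise_sd: float | None = None,
) -> tuple[dict[str, DropTrack], DropTruth]:
    """Render the synchronization drop: a cube slides down a rod, free-falls,
    and bounces once; each camera records the vertical pixel trace on its own
    (fractionally offset) frame grid.

    Cameras view the drop with a horizontal optical axis, so the vertical
    pixel coordinate is an affine image of cube height and each flight phase
    is an exact parabola in time.  ``noise_sd`` defaults to the scene's
    ``pixel_noise_sd``.
    """
    config.validate()
    if drop_height <= 0:
        raise ConfigurationError("drop_height must be positive")
    if not 0.0 <= restitution < 1.0:
        raise ConfigurationError("restitution must lie in [0, 1)")
    rng = np.random.default_rng(config.rng_seed)
    sd = config.pixel_noise_sd if noise_sd is None else noise_sd
    offsets = config.offsets()
    fps = config.frame_rate

    t0 = rest_frames / fps
    t_impact = t0 + math.sqrt(2.0 * drop_height / GRAVITY)
    v_impact = GRAVITY * (t_impact - t0)
    t_end = t_impact + (
        2.0 * restitution * v_impact / GRAVITY if restitution > 0 else 4.0 / fps
    )

    def height(t: float) -> float:
        if t <= t0:
            return drop_height
        if t <= t_impact:
            return drop_height - 0.5 * GRAVITY * (t - t0) ** 2
        if restitution == 0:  # dead drop: the cube stays on the damper
            return 0.0
        dt = t - t_impact
        return restitution * v_impact * dt - 0.5 * GRAVITY * dt * dt

    cy = config.image_size[1] / 2.0
    focal = pixels_per_metre * camera_distance
    cam_z = drop_height / 2.0

    tracks: dict[str, DropTrack] = {}
    events: dict[str, float] = {}
    for i in range(config.n_cameras):
        cid = f"cam{chr(ord('A') + i)}"
        frames, ys = [], []
        f = 0
        while True:
            t = (f + offsets[i]) / fps
            if t > t_end:
                break
            y_px = cy + focal * (cam_z - height(t)) / camera_distance
            if sd > 0:
                y_px += rng.normal(0.0, sd)
            frames.append(f)
            ys.append(y_px)
            f += 1
        tracks[cid] = DropTrack(camera_id=cid, frames=np.array(frames), y=np.array(ys))
        events[cid] = t_impact * fps - offsets[i]

    ref = min(events)
    truth = DropTruth(
        impact_time=t_impact,
        events=events,
        offsets={c: e - events[ref] for c, e in events.items()},
    )
    return tracks, truth
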