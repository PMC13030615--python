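"""Shared fixtures: small seeded scenes and synthetic camera factories."""

from __future__ import annotations

import numpy as np
import pytest

from ptzmocap import scene_sim
from ptzmocap.types import Correspondence, ProjectionMatrix, SceneConfig


def clean_config(**overrides) -> SceneConfig:
    """A small all-noise-off scene configuration."""
    defaults = dict(
        n_cameras=4,
        n_refpoints=60,
        n_frames=40,
        pixel_noise_sd=0.0,
        ref_dropout_prob=0.0,
        id_dropout_prob=0.0,
        keypoint_noise_sd=0.0,
        rng_seed=1,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, offset-free 4-camera trial with exact ground truth."""
    return scene_sim.generate_scene(clean_config())


def random_camera(rng: np.random.Generator, scale: float = 10.0) -> ProjectionMatrix:
    """A physically plausible random pinhole camera looking at the origin."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    centre = -scale * direction * rng.uniform(2.0, 4.0)
    fwd = direction
    right = np.cross(fwd, rng.normal(size=3))
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.stack([right, down, fwd])
    f = rng.uniform(1000.0, 5000.0)
    K = np.array([[f, 0, 1920.0], [0, f, 1080.0], [0, 0, 1.0]])
    P = K @ np.hstack([R, -R @ centre[:, None]])
    return ProjectionMatrix(P=P / np.linalg.norm(P))


def random_correspondences(
    rng: np.random.Generator, P: ProjectionMatrix, n: int, scale: float = 10.0
) -> list[Correspondence]:
    """General-position points in front of the camera, projected exactly."""
    corrs = []
    rid = 0
    while len(corrs) < n:
        world = rng.uniform(-scale, scale, size=3)
        uv, depth = P.project(world)
        if depth <= 0:
            continue
        corrs.append(Correspondence(ref_id=rid, world=world, image=uv))
        rid += 1
    return corrs
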