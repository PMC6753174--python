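"""Shared fixtures: small fast synthetic scenes and pre-rendered videos."""

import numpy as np
import pytest

from freezeframe import (
    MotionTrace,
    SceneConfig,
    generate,
    make_schedule,
    motion_trace,
)

# Small frames keep unit tests fast; below-minimum-size warnings are expected.
pytestmark = pytest.mark.filterwarnings("ignore:.*below the characterized minimum.*")


def small_scene(**overrides) -> SceneConfig:
    defaults = dict(
        width=120, height=90, fps=5.0, blob_axes=(12, 8), jitter_px=4,
        blob_intensity=220, background_intensity=30, noise_sd=0.0, seed=0,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def mixed_video():
    """60-s half-freezing synthetic recording at small scale."""
    schedule = make_schedule(60, 0.5, 8, seed=3)
    return generate(schedule, small_scene(seed=3))


@pytest.fixture(scope="session")
def mixed_trace(mixed_video) -> MotionTrace:
    return motion_trace(mixed_video.frames, mixed_video.scene.fps)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
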