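import dataclasses

import numpy as np
import pytest

from siamvitals.model import ModelSpec
from siamvitals.preprocess import LandmarkFrame
from siamvitals.synthetic import SimConfig, generate_clip


def tiny_model_spec(**overrides) -> ModelSpec:
    """A one-stage spec small enough for gradient checks and smoke training."""
    base = dict(
        n_frames=16,
        roi_shape=(6, 8, 3),
        branch_widths=(4,),
        pointwise_widths=(4,),
        embed_dim=6,
        resp_hidden=8,
        multitask=True,
        seed=0,
    )
    base.update(overrides)
    return ModelSpec(**base)


def tiny_sim_config(**overrides) -> SimConfig:
    """Small fast clips matching :func:`tiny_model_spec` (16 s at 8 FPS)."""
    base = dict(n_frames=128, roi_height=6, roi_width=8, fps=8.0)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_clip():
    """One full-size synthetic clip (600 frames, 40x140, 20 FPS)."""
    return generate_clip(SimConfig(seed=11))


@pytest.fixture
def frontal_landmarks() -> LandmarkFrame:
    """A constructed frontal-face 68-point template with known coordinates.

    Jaw contour spans x in [20, 80] with the chin (point 8) at (50, 90);
    eyebrows (17-26) lie on the line y = 30 spanning x in [30, 70]; the nose
    tip (point 33) sits at (50, 60). All remaining points fall inside the
    face so they never define the hull extremes.
    """
    pts = np.full((68, 2), (50.0, 70.0))
    jaw_x = np.linspace(20, 80, 17)
    jaw_y = np.concatenate([np.linspace(40, 90, 9), np.linspace(90, 40, 9)[1:]])
    pts[0:17] = np.column_stack([jaw_x, jaw_y])
    pts[8] = (50.0, 90.0)
    pts[17:27] = np.column_stack([np.linspace(30, 70, 10), np.full(10, 30.0)])
    pts[27:31] = np.column_stack([np.full(4, 50.0), np.linspace(40, 55, 4)])
    pts[31:36] = np.column_stack([np.linspace(44, 56, 5), np.full(5, 60.0)])
    pts[33] = (50.0, 60.0)
    pts[36:48] = np.column_stack(
        [np.linspace(35, 65, 12), np.full(12, 38.0)]
    )
    pts[48:68] = np.column_stack(
        [np.linspace(40, 60, 20), np.full(20, 75.0)]
    )
    return LandmarkFrame(points=pts, frame_index=0)


def shift_landmarks(lm: LandmarkFrame, dx: float = 0.0, dy: float = 0.0) -> LandmarkFrame:
    return dataclasses.replace(lm, points=lm.points + np.array([dx, dy]))
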