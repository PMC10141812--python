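import numpy as np
import pytest

from facepulse.io_formats import LandmarkFrame
from facepulse.synth_data import SynthConfig, _eye_model_points, _face_points, simulate_session

_RIGHT_EYE_CENTER = np.array([570.0, 320.0])
_LEFT_EYE_CENTER = np.array([710.0, 320.0])


def make_template_frame(
    frame_index: int = 0,
    eye_open: float = 1.0,
    mouth_inner_ry: float = 2.0,
    gaze=(0.0, 0.0),
    head=(0.0, 0.0, 0.0),
    success: bool = True,
    fps: float = 30.0,
) -> LandmarkFrame:
    """A deterministic neutral-face frame built from the generator's template."""
    face = _face_points(eye_open, mouth_inner_ry, 1.0)
    eye = np.vstack(
        [
            _eye_model_points(_RIGHT_EYE_CENTER, eye_open, np.zeros(2)),
            _eye_model_points(_LEFT_EYE_CENTER, eye_open, np.zeros(2)),
        ]
    )
    return LandmarkFrame(
        frame_index=frame_index,
        timestamp=frame_index / fps,
        confidence=0.98,
        success=success,
        face_points=face,
        eye_points=eye,
        gaze=np.asarray(gaze, dtype=float),
        head_rotation=np.asarray(head, dtype=float),
    )


@pytest.fixture
def template_frame() -> LandmarkFrame:
    return make_template_frame()


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 40 s, 2-utterance session: cheap enough for repeated use."""
    return SynthConfig(duration_s=40.0, n_utterances=2, seed=7, pulse_missing_rate=0.0)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def medium_labeled_dataset():
    """A preprocessable labeled dataset from a 120 s session (session-scoped)."""
    from facepulse.labeling import label_dataset
    from facepulse.temporal_features import build_feature_table

    session, truth = simulate_session(SynthConfig(duration_s=120.0, n_utterances=6, seed=21))
    table = build_feature_table(session)
    return label_dataset(table, session.annotations), truth
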