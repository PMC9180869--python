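import numpy as np
import pytest

from evacpanic import EyeRecording, build_timeline


@pytest.fixture(scope="session")
def timeline():
    return build_timeline()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_eye_recording(
    n=600,
    rate=60.0,
    pupil=None,
    fixation=None,
    saccade=None,
    gaze_x=None,
    gaze_y=None,
):
    """Small hand-crafted recording; both eyes identical unless overridden."""
    pupil = np.full(n, 20.0) if pupil is None else np.asarray(pupil, float)
    n = len(pupil)
    fixation = np.ones(n, bool) if fixation is None else np.asarray(fixation, bool)
    saccade = np.zeros(n, bool) if saccade is None else np.asarray(saccade, bool)
    gaze_x = np.full(n, 100.0) if gaze_x is None else np.asarray(gaze_x, float)
    gaze_y = np.full(n, 100.0) if gaze_y is None else np.asarray(gaze_y, float)
    return EyeRecording(
        pupil_left=pupil,
        pupil_right=pupil.copy(),
        fixation_left=fixation,
        fixation_right=fixation.copy(),
        saccade_left=saccade,
        saccade_right=saccade.copy(),
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        rate=rate,
    )
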