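import numpy as np
import pytest

import acromotion as am


@pytest.fixture
def default_cfg():
    return am.MotionConfig()


@pytest.fixture
def noiseless_cfg():
    return am.MotionConfig(noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture
def recording_csv(tmp_path, default_cfg):
    """A simulated landmark CSV on disk plus its ground truth."""
    frames, truth = am.simulate_recording(default_cfg)
    path = tmp_path / "recording.csv"
    am.write_landmark_csv(frames, path)
    return path, truth


def circle_points(center, radius, angles_deg):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.column_stack(
        [center[0] + radius * np.cos(a), center[1] + radius * np.sin(a)]
    )


@pytest.fixture
def make_circle_points():
    return circle_points
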