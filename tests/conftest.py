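import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trophnet.tracking import DetectionTable, validate_detections

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_detections(rows, trial_id="T1") -> DetectionTable:
    """Build a validated detection table from (frame, time, ant, x, y, theta)."""
    df = pd.DataFrame(rows, columns=["frame", "time_s", "ant_id", "x_px", "y_px", "theta_rad"])
    df.insert(0, "trial_id", trial_id)
    return validate_detections(df, trial_id=trial_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_ant_frame():
    """One co-detected frame with the two ants a fixed distance apart."""

    def build(distance, theta=0.0):
        return make_detections([
            (0, 0.0, "a00", 0.0, 0.0, theta),
            (0, 0.0, "a01", distance, 0.0, theta),
        ])

    return build
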