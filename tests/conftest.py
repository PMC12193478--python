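import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitvar import PoseSequence
from gaitvar.pose_io import LEFT_FOOT, N_KEYPOINTS, RIGHT_FOOT

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_sequence(
    left_xy,
    right_xy=None,
    left_conf=None,
    right_conf=None,
    subject_id="S001",
    trial_id="t1",
):
    """Build a PoseSequence with explicit foot coordinates/confidences.

    Non-foot keypoints sit at a fixed torso layout with confidence 1.
    """
    left_xy = np.asarray(left_xy, dtype=float).reshape(-1, 2)
    n = len(left_xy)
    right_xy = (
        left_xy + [4.0, 12.0]
        if right_xy is None
        else np.asarray(right_xy, dtype=float).reshape(-1, 2)
    )
    kp = np.zeros((n, N_KEYPOINTS, 3))
    kp[:, :, 0] = 50.0
    kp[:, :, 1] = 80.0
    kp[:, :, 2] = 1.0
    kp[:, LEFT_FOOT, :2] = left_xy
    kp[:, RIGHT_FOOT, :2] = right_xy
    kp[:, LEFT_FOOT, 2] = 1.0 if left_conf is None else np.asarray(left_conf, float)
    kp[:, RIGHT_FOOT, 2] = 1.0 if right_conf is None else np.asarray(right_conf, float)
    return PoseSequence(subject_id=subject_id, trial_id=trial_id, keypoints=kp)


@pytest.fixture
def sequence_factory():
    return make_sequence
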