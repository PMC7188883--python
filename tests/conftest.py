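import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tiltadapt.device import make_schedule
from tiltadapt.io import TrialLog

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule_cw():
    """Within-block CW angle sequence (the triangle, 40 trials)."""
    return make_schedule("CW").block_angles("CW")


@pytest.fixture(scope="session")
def delayed_series(schedule_cw):
    """Noiseless delayed-gain adaptation curve builder (1-based delay semantics)."""

    def build(amp: float, delay: int) -> np.ndarray:
        x = np.zeros(40)
        for t in range(1, 41):
            if t - delay >= 1:
                x[t - 1] = amp * schedule_cw[t - 1 - delay]
        return x

    return build


@pytest.fixture
def make_log():
    """Build a minimal TrialLog from cursor coordinates for scoring tests."""

    def build(x, y, fs=200.0, rotation=0.0, target=90.0, block="CW", block_trial=1):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(x)
        return TrialLog(
            subject_id="t01", group="test", block=block, trial=21,
            block_trial=block_trial, rotation_deg=rotation, target_angle_deg=target,
            frame=np.arange(n), time_s=np.arange(n) / fs,
            accel_x=np.zeros(n), accel_y=np.zeros(n),
            cursor_x_mm=x, cursor_y_mm=y,
        )

    return build
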