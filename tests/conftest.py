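import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from parpbridge.calibration import CalibrationPoint  # noqa: E402


@pytest.fixture
def exact_line_points():
    """Eight-level calibration on an exact line y = 0.002 x (niraparib range)."""
    nominals = [60, 120, 300, 600, 1200, 1800, 2400, 3000]
    return [
        CalibrationPoint(chr(ord("H") - i), float(x), 0.002 * x)
        for i, x in enumerate(nominals)
    ]


@pytest.fixture
def noisy_calibration_table():
    """Fixed 16-point duplicate-calibrator table with proportional noise."""
    rng = np.random.default_rng(42)
    nominals = np.repeat([60, 120, 300, 600, 1200, 1800, 2400, 3000], 2).astype(float)
    responses = 0.002 * nominals * (1 + rng.normal(0, 0.05, nominals.size))
    return nominals, responses
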