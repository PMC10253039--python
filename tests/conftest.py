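import numpy as np
import pytest

from applegrade.features import CalibrationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calib():
    return CalibrationConfig(mm_per_px=0.35)


def disk_mask(radius: int, pad: int = 6) -> np.ndarray:
    """Rasterized disk: pixel centres within ``radius`` of the canvas centre."""
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    return ((xx + 0.5 - n / 2) ** 2 + (yy + 0.5 - n / 2) ** 2) <= radius**2


def ellipse_mask(a: float, b: float, pad: int = 6) -> np.ndarray:
    w, h = int(np.ceil(2 * a)) + 2 * pad, int(np.ceil(2 * b)) + 2 * pad
    yy, xx = np.mgrid[0:h, 0:w]
    return (((xx + 0.5 - w / 2) / a) ** 2 + ((yy + 0.5 - h / 2) / b) ** 2) <= 1.0
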