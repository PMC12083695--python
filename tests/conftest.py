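import numpy as np
import pytest

from isoipipe.ratio import TrialStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def flat_stack():
    """10 constant raw frames, onset at frame 5."""
    frames = np.full((10, 8, 8), 1000.0)
    return TrialStack(frames=frames, frame_duration_ms=100.0, onset_frame=5)


def gaussian_blob(shape, center, sigma, amplitude):
    """Analytic 2-D Gaussian FC image (shared test helper)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma**2)
    )


def gaussian_level_area(amplitude, sigma, threshold):
    """Closed-form suprathreshold area of a Gaussian blob, in pixels."""
    return 2.0 * np.pi * sigma**2 * np.log(abs(amplitude) / threshold)
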