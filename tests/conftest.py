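import numpy as np
import pytest

from wormquant.calcium import Roi, TwoChannelStack


def gaussian_frame(shape, center, sigma=3.0, amplitude=100.0, offset=0.0):
    rr = np.arange(shape[0], dtype=float)[:, None]
    cc = np.arange(shape[1], dtype=float)[None, :]
    g = amplitude * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))
    return g + offset


def static_cell_stack(n_frames=40, yellow_scale=None):
    """Time-constant stack with a central cell; ratio is constant over time.

    ``yellow_scale`` optionally modulates the yellow cell signal per frame.
    """
    cell = gaussian_frame((32, 32), (15.5, 15.5), sigma=3.0, amplitude=100.0)
    cyan = np.stack([cell + 5.0] * n_frames)
    if yellow_scale is None:
        yellow_scale = np.ones(n_frames)
    yellow = np.stack([1.6 * s * cell + 5.0 for s in yellow_scale])
    return TwoChannelStack(cyan=cyan, yellow=yellow, frame_rate=10.0)


@pytest.fixture
def flat_stack():
    """Two-channel stack of a static cell with time-constant channels."""
    return static_cell_stack()


@pytest.fixture
def center_roi():
    return Roi(center=(15.5, 15.5), half_height=5, half_width=5)


@pytest.fixture
def gaussian_spot_stack():
    """Stationary symmetric Gaussian spot at (20, 20) in both channels."""
    frames = np.stack([gaussian_frame((41, 41), (20.0, 20.0), offset=5.0) for _ in range(20)])
    return TwoChannelStack(cyan=frames, yellow=1.2 * frames, frame_rate=10.0)
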