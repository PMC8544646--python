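import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning, module="mvpac")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_signal():
    """Unit AM tone at 45 Hz with a slow envelope, fs = 128 Hz."""
    fs = 128.0
    t = np.arange(128) / fs
    envelope = 1.0 + 0.6 * np.sin(2 * np.pi * 1.5 * t)
    return envelope * np.cos(2 * np.pi * 45.0 * t), envelope, fs
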