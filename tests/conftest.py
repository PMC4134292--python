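import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wavecon.spike_io import Recording, SpikeTrain
from wavecon.wavelet import WaveletConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A 311-bin scale-2-like configuration that pads to 512 bins.

    Small enough for O(N^2) direct-summation oracles while keeping the
    edge-padding rule (100-bin averages) exercised.
    """
    return WaveletConfig(
        bin_width=500e-6,
        transform_window=155 * 500e-6,
        peak_window=100 * 500e-6,
        freq_lo=2.0,
        freq_hi=100.0,
        n_freq=21,
    )


@pytest.fixture
def three_neuron_recording():
    return Recording(
        trains=(
            SpikeTrain(1, np.array([0.2, 0.5, 1.75]), (0.0, 0.0)),
            SpikeTrain(2, np.array([0.9]), (60.0, 0.0)),
            SpikeTrain(3, np.array([0.1, 1.1, 1.2, 1.9]), None),
        ),
        duration=2.0,
        region_label="cortex",
    )
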