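import numpy as np
import pytest

from respforecast import generate_breathing, pattern_presets


@pytest.fixture(scope="session")
def steady_signal():
    """One minute of jitter-free, noise-free steady breathing at 26 Hz."""
    return generate_breathing(pattern_presets("steady"), 60.0, 26.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
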