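import numpy as np
import pytest

from mammomc import spectrum_for_beam


@pytest.fixture(scope="session")
def beam_26al():
    """The 26 kVp W/Al clinical beam anchored to HVL 0.423 mm Al."""
    spec, quality = spectrum_for_beam(26, "Al", 0.423)
    return spec, quality


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
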