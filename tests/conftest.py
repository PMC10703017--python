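import numpy as np
import pytest

from pdeeg.synth import DEFAULT_BAND_POWERS, SyntheticCohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort: 4 channels at 256 Hz, 10 s per subject."""
    control = {**DEFAULT_BAND_POWERS, "gamma": 0.0}
    pd = {**control, "beta": control["beta"] * 2.0}
    return SyntheticCohortSpec(n_pd=2, n_hc=2, n_channels=4, fs=256.0,
                               duration=10.0,
                               band_powers={"control": control, "pd": pd},
                               seed=7)
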