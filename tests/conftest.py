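import numpy as np
import pytest

from glomkit.synthetic import SimImagingConfig


@pytest.fixture
def small_config():
    """A fast trace-mode experiment: 5 glomeruli, 3 odors, 3 repeats."""
    return SimImagingConfig(
        n_glomeruli=5,
        n_odors=3,
        n_repeats=3,
        blank_trials=2,
        odor_duration=5.0,
        baseline_duration=5.0,
        inter_trial_gap=10.0,
        frame_rate=4.0,
        noise_sd=0.01,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
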