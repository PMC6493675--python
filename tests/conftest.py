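import numpy as np
import pytest

from sabr import (
    EpochMatrix,
    NoiseModel,
    make_template,
    simulate_epochs,
)


@pytest.fixture(scope="session")
def quiet_template():
    return make_template("short50")


@pytest.fixture(scope="session")
def clean_epochs(quiet_template):
    """Near-noiseless quiet recording: template recovery ground truth."""
    return simulate_epochs(
        quiet_template, 64, NoiseModel(sd_uV=0.01), seed=101
    )


@pytest.fixture(scope="session")
def noisy_epochs(quiet_template):
    """Realistic quiet recording at the default noise level."""
    return simulate_epochs(
        quiet_template, 2000, NoiseModel(sd_uV=2.5), seed=202
    )


@pytest.fixture()
def tiny_matrix():
    """Deterministic 6-sample x 4-epoch integer matrix for hand oracles."""
    data = np.array(
        [
            [1.0, 2.0, 0.0, 3.0],
            [2.0, 1.0, 1.0, 2.0],
            [4.0, 3.0, 5.0, 4.0],
            [1.0, 0.0, 2.0, 1.0],
            [0.0, 1.0, -1.0, 0.0],
            [2.0, 2.0, 3.0, 1.0],
        ]
    )
    return EpochMatrix(
        data=data,
        sample_rate_hz=1000.0,
        pre_stim_ms=0.0,
        polarity=np.array([0, 1, 0, 1]),
        condition="quiet",
    )


def _make_noise_epochs(n_epochs=200, seed=0, sd=2.5, epoch_ms=80.0):
    return simulate_epochs(
        None, n_epochs, NoiseModel(sd_uV=sd), seed=seed, epoch_ms=epoch_ms
    )


@pytest.fixture(scope="session")
def noise_epochs_factory():
    """Factory for no-sound (pure background noise) recordings."""
    return _make_noise_epochs
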