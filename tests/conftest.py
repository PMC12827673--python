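import numpy as np
import pytest

from amanet import (
    AugConfig,
    ModelConfig,
    RawTrialSet,
    SyntheticSpec,
    generate_trialset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def easy_small_spec():
    """Six-channel, two-class, high-SNR spec small enough for fast tests."""
    return SyntheticSpec(
        n_channels=6,
        sfreq=250.0,
        n_samples=1000,
        n_trials_per_class=10,
        n_classes=2,
        class_bands=(((10.0, 2.0, 1.0),), ((10.0, 2.0, 1.0),)),
        mixing=(
            (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            (0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
        ),
        noise_sd=0.2,
        seed=7,
    )


@pytest.fixture
def easy_small_trials(easy_small_spec):
    return generate_trialset(easy_small_spec)


@pytest.fixture
def tiny_model_config():
    """A config small enough for finite-difference gradient checks."""
    return ModelConfig(
        in_channels=3,
        in_samples=32,
        n_classes=2,
        F1=2,
        D=2,
        F2=4,
        ms_kernels=(2, 3, 4),
        K1=8,
        K2=4,
        eca_k=3,
        fc_width=3,
        dropout=0.0,
        seed=3,
    )


@pytest.fixture
def gaussian_trialset(rng):
    """Two-class trials with diagonal covariances diag(4,1) and diag(1,4)."""
    n_per = 30
    t = 200
    d0 = rng.standard_normal((n_per, 2, t)) * np.array([2.0, 1.0])[None, :, None]
    d1 = rng.standard_normal((n_per, 2, t)) * np.array([1.0, 2.0])[None, :, None]
    data = np.concatenate([d0, d1])
    labels = np.array([0] * n_per + [1] * n_per)
    return RawTrialSet(data, labels, sfreq=100.0)
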