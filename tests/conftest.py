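import numpy as np
import pytest

from gaitwrench.core import scale_subject
from gaitwrench.ppca import FeatureLayout
from gaitwrench.synth import ANGLE_CHANNELS, GeneratorConfig, generate_dataset, normalized_cycles


@pytest.fixture(scope="session")
def subject80():
    """An 80 kg / 1.80 m reference subject on the bundled table."""
    return scale_subject(80.0, 1.80, subject_id="ref80")


@pytest.fixture(scope="session")
def default_layout():
    return FeatureLayout.default(list(ANGLE_CHANNELS))


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """A small noisy cohort shared by several estimator tests."""
    cfg = GeneratorConfig(n_subjects=5, cycles_per_subject=15, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_noisy_cycles(small_noisy_dataset):
    return normalized_cycles(small_noisy_dataset)


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic regime: no noise, no latent variation, no offsets."""
    return GeneratorConfig(
        n_subjects=2, cycles_per_subject=2,
        mass_sd=0.0, height_sd=0.0, speed_sd=0.0,
        noise_sd_grf=0.0, noise_sd_kin=0.0,
        latent_sd=(0.0,) * 5,
        subject_offset_sd_grf=0.0, subject_offset_sd_kin=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
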