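import numpy as np
import pytest

from mitransfer.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 12 trials/class, 4 channels: fast end-to-end fixture."""
    cfg = SyntheticConfig(
        n_subjects=3, n_trials_per_class=12, n_channels=4, seed=7
    )
    return generate_cohort(cfg)


def random_spd(rng, k, scale=1.0):
    """Random symmetric positive-definite matrix with unit-order spectrum."""
    a = rng.normal(size=(k, k))
    return a @ a.T * scale / k + 0.1 * np.eye(k)
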