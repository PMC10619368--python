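import numpy as np
import pytest

from groupdecode import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 3 classes x 4 trials of 6-channel, 32-sample epochs."""
    cfg = GeneratorConfig(
        n_subjects=2, n_classes=3, n_trials_per_class=4, C=6, T=32, t0=0.0,
        planted_channels=(0, 1, 2), planted_window=(0.02, 0.1),
        planted_band=(10.0, 15.0), seed=7,
    )
    dataset, layout, truth = generate_dataset(cfg)
    return dataset, layout, truth


class IdentityRng:
    """An rng stub whose permutations are always the identity."""

    def permutation(self, n):
        if np.isscalar(n):
            return np.arange(n)
        return np.asarray(n)

    def standard_normal(self, shape):  # pragma: no cover - not used by identity paths
        return np.zeros(shape)


@pytest.fixture
def identity_rng():
    return IdentityRng()
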