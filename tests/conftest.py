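import pytest

from probreason import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default generator conditions: 30 participants, noise sd 0.05, seed 11."""
    dataset, truth = generate_dataset(SyntheticConfig(seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def coherent_dataset():
    """Idealized coherent reasoners: no noise, no form-based blending."""
    config = SyntheticConfig(
        n_participants=250, noise_sd=0.0, lambda_dist=("point", 0.0), seed=3
    )
    dataset, truth = generate_dataset(config)
    return dataset, truth
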