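import numpy as np
import pytest

from cprlearn import ModelParams, ModelSpec, generate_agent_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def social_dataset():
    """Small social-condition cohort generated by the social model."""
    return generate_agent_dataset(
        ModelSpec("social"),
        ModelParams(alpha=0.3, beta=2.0, theta_s=0.5),
        n_subjects=4,
        condition="social",
        seed=101,
    )


@pytest.fixture(scope="session")
def nonsocial_dataset():
    """Small nonsocial-condition cohort generated by the sustainability model."""
    return generate_agent_dataset(
        ModelSpec("nonsocial"),
        ModelParams(alpha=0.3, beta=2.0, theta_n=0.5),
        n_subjects=4,
        condition="nonsocial",
        seed=102,
    )
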