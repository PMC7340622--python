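import pytest

from exclusim import ScenarioConfig, add_ue_columns, sample_cohort


@pytest.fixture(scope="session")
def config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def cohort(config):
    """One default cohort with UE columns, shared across read-only tests."""
    return add_ue_columns(sample_cohort(config, seed=7), config)


@pytest.fixture(scope="session")
def degenerate_config(config):
    """Noise-free and no adaptive drop: the normalized outcome is exactly
    the programmed arm effect."""
    return config.noise_free().model_copy(update=dict(adaptive_drop_per_pct=0.0))
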