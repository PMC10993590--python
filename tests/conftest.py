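import numpy as np
import pytest

from xairob.chem_data import (
    NITRO_ALERT_SMARTS,
    AlertSet,
    generate_synthetic_molecules,
    tokenize,
)
from xairob.transformer_models import ModelConfig, build_model


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Desk-scale two-layer encoder used across model/attribution tests."""
    return ModelConfig(max_len=40, embed_dim=32, heads=4, layers=2, ff_mult=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=1)


@pytest.fixture(scope="session")
def nitro_alerts() -> AlertSet:
    return AlertSet(entries=(("nitro", NITRO_ALERT_SMARTS),))


@pytest.fixture(scope="session")
def synthetic_corpus():
    """Labelled corpus with a planted nitro alert and no label noise."""
    return generate_synthetic_molecules(
        60, seed=11, planted_alert=NITRO_ALERT_SMARTS, noise=0.0
    )


@pytest.fixture
def short_seq():
    return tokenize("CCOc1ccccc1", pad_to=16)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
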