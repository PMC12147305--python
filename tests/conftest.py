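import logging

import numpy as np
import pytest

from circmi.config import PipelineConfig
from circmi.synthetic_data import SyntheticConfig, generate

logging.getLogger("circmi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-rule dataset: 40 circRNAs x 16 miRNAs, noise-free."""
    cfg = SyntheticConfig(
        n_circ=40,
        n_mi=16,
        circ_len_range=(120, 300),
        target_density=0.08,
        label_noise=0.0,
        rng_seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Down-scaled pipeline config for quick end-to-end unit tests."""
    return PipelineConfig(
        embed_dim=16,
        sg_epochs=1,
        sae_sizes=(32, 16, 8),
        sae_epochs=3,
        grarep_orders=2,
        grarep_rank=4,
        max_iter=150,
        n_folds=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
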