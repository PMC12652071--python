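import numpy as np
import pytest

from layerprune import (
    EncoderConfig,
    FineTuneConfig,
    MotifModel,
    build_tiny_encoder,
    generate_dataset,
)


@pytest.fixture(scope="session")
def micro_splits():
    """Tiny planted-motif splits for fast training tests."""
    return generate_dataset(
        n_train=120, n_val=40, n_test=60, L=32,
        motif_model=MotifModel(placement_window=4),
        seed=11,
    )


@pytest.fixture()
def micro_encoder():
    """A 2-layer, width-16 encoder that trains in seconds."""
    cfg = EncoderConfig(n_layers=2, d_model=16, n_heads=2, d_ff=24, max_len=40)
    return build_tiny_encoder(cfg, seed=7)


@pytest.fixture()
def fast_cfg():
    return FineTuneConfig(
        mode="fixed_epochs", fixed_epochs=1, learning_rate=1e-3,
        batch_size=32, seed=0,
    )
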