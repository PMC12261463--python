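import numpy as np
import pytest

from bompool.pooling import PoolingParams
from bompool.providers import (
    SequenceRecord,
    SyntheticEmbeddingConfig,
    SyntheticEmbeddingProvider,
    embed,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def provider():
    """Default deterministic synthetic embedding provider."""
    return SyntheticEmbeddingProvider()


@pytest.fixture
def clean_provider():
    """Noise-free, mixing-free provider: rows depend on residue letter only."""
    return SyntheticEmbeddingProvider(
        SyntheticEmbeddingConfig(mixing_weight=0.0, noise_sd=0.0)
    )


@pytest.fixture
def embed_seq(provider):
    def _embed(residues, sid="seq"):
        return embed(SequenceRecord(sid, residues), provider)

    return _embed


@pytest.fixture
def make_params():
    """Factory for seeded Q/K/V pooling transforms."""

    def _make(d, d_pool=None, hidden=None, seed=7, **kw):
        return PoolingParams.init(d, d_pool, hidden, seed=seed, **kw)

    return _make


@pytest.fixture
def random_matrix(rng):
    def _make(l, d):  # noqa: E741
        return rng.normal(size=(l, d))

    return _make
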