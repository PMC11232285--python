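import numpy as np
import pytest

import ctgansurv as cs


@pytest.fixture(scope="session")
def small_pair():
    """Two tiny domains with shared latent structure (40 genes)."""
    cfg = cs.SyntheticConfig(n_a=120, n_b=100, n_genes=40, n_informative=8, seed=7)
    return cs.simulate_pair(cfg)


@pytest.fixture(scope="session")
def tiny_model(small_pair):
    """A briefly-trained small model over the 40-gene fixture."""
    dom_a, dom_b, _ = small_pair
    d = 41
    model = cs.CtganModel(cs.GeneratorSpec(d, hidden_width=32),
                          cs.DiscriminatorSpec(d, (32, 16, 8)),
                          dom_a.expression.gene_ids, seed=3)
    cfg = cs.TrainConfig(epochs=3, n_repeats=1, batch_size=32, seed=3)
    history = cs.train(model, dom_a, dom_b, cfg)
    return model, history


class IdentityNet:
    """Stands in for a generator that maps every vector to itself."""

    def __call__(self, x, training=False):
        return np.asarray(x, dtype=float).copy()


class FakeModel:
    """Model facade whose generators are arbitrary callables (for transfer tests)."""

    def __init__(self, gene_ids, g_ab=None, g_ba=None):
        self.gene_ids = list(gene_ids)
        self.networks = {"g_ab": g_ab or IdentityNet(), "g_ba": g_ba or IdentityNet()}


@pytest.fixture
def identity_model(small_pair):
    dom_a, _, _ = small_pair
    return FakeModel(dom_a.expression.gene_ids)
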