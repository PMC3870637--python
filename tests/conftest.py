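import numpy as np
import pytest

import gsgprobit as g


@pytest.fixture
def tiny():
    """Frozen rank-deficient 4x3 instance (third gene duplicates the first)."""
    return g.make_tiny_fixture()


@pytest.fixture
def tiny_cfg():
    return g.ModelConfig(h=1.0, pi=0.2)


@pytest.fixture
def small_synth():
    """Small strong-signal dataset: 3 true genes among 12, n=40."""
    spec = g.SyntheticSpec(n_train=40, n_test=10, p=12,
                           true_support=(0, 1, 2), seed=11)
    train, test, truth = g.generate(spec)
    return train, test, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
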