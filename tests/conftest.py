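import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `reference` importable

from typedlda import ModelConfig, fit, simulate_corpus


@pytest.fixture(scope="session")
def small_sim():
    """A small two-type simulated corpus with its ground truth."""
    corpus, truth = simulate_corpus(
        n_topics=3,
        type_sizes={"physician": 40, "nursing": 35},
        n_docs=30,
        doc_length=60,
        alpha=0.4,
        beta=0.08,
        seed=11,
    )
    return corpus, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A converged fit of the small simulated corpus at the true K."""
    corpus, _ = small_sim
    return fit(corpus, ModelConfig(n_topics=3, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
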