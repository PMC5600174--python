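"""Shared fixtures: small synthetic worlds and scaled-down boosting settings."""

import numpy as np
import pytest

from finchsdm import suitability, synthetic


@pytest.fixture(scope="session")
def fast_hp():
    """Boosting settings scaled for test runtime (protocol unchanged)."""
    return suitability.BCTHyperParams(
        learning_rate=0.05, tree_step=25, max_trees=300, patience=3,
    )


@pytest.fixture(scope="session")
def fixed_hp():
    """Fixed tree count: skips CV selection entirely."""
    return suitability.BCTHyperParams(learning_rate=0.05, n_trees=100)


@pytest.fixture(scope="session")
def small_stack():
    cfg = synthetic.LandscapeConfig(shape=(50, 50), seed=101)
    return synthetic.generate_landscape(cfg)


@pytest.fixture(scope="session")
def truth_params():
    return synthetic.TruthParams()


@pytest.fixture(scope="session")
def small_truth(small_stack, truth_params):
    return synthetic.true_suitability(small_stack, truth_params)


@pytest.fixture(scope="session")
def small_nests(small_truth):
    return synthetic.simulate_nests(small_truth, 59, seed=202)


@pytest.fixture(scope="session")
def small_sample(small_stack, small_nests):
    bg = suitability.sample_background(small_stack, 59, seed=303, exclude=small_nests)
    return suitability.build_sample_set(small_stack, small_nests, bg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
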