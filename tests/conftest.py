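import numpy as np
import pytest

from forgesel import PipelineConfig, PlantedDatasetSpec, generate_planted


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset (40 actives + 120 decoys, 120 features)."""
    spec = PlantedDatasetSpec(m=40, d=120, n_informative=10, n_real_cols=20, seed=7)
    return generate_planted(spec)


@pytest.fixture()
def fast_cfg():
    """A scaled-down pipeline configuration for unit tests."""
    return PipelineConfig(trees=30, epochs=10, k_selected=30, cv_folds=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
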