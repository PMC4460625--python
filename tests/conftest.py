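import numpy as np
import pytest

import ppianet as pn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_data():
    """Small planted-edge dataset for fast LP/evaluation tests.

    8 samples per class keeps every LP under a tenth of a second; alpha/C for
    LP solves on this fixture must be passed explicitly because the package
    defaults assume ~30 samples per class.
    """
    spec = pn.SyntheticSpec(
        n_genes=24, n_edges=30, n_classes=2, samples_per_class=8,
        n_planted_edges=3, seed=7,
    )
    return pn.generate_dataset(spec)


@pytest.fixture
def random_expr(rng):
    """20 genes x 10 samples of lognormal values with IDs."""
    values = rng.lognormal(0.0, 0.5, size=(20, 10))
    return pn.ExpressionMatrix(
        [f"G{i:02d}" for i in range(20)], [f"S{j}" for j in range(10)], values
    )
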