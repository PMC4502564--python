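import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dupliphy import ExpressionMatrix, GeneratorConfig, simulate_dataset
from dupliphy.config import CANONICAL_TISSUES

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        {
            "cerebrum-F": [10.0, 0.5, 0.0, 5.0],
            "heart-F": [30.0, 0.9, 0.0, 5.0],
            "testis": [60.0, 0.99, 1.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(species="human", data=data)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small but complete synthetic bundle shared across pipeline tests."""
    config = GeneratorConfig(
        seed=7, n_single_copy=60, n_trios_per_class=8, n_unresolved_families=3
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def tiny_bundle_dir(tmp_path_factory, tiny_bundle):
    outdir = tmp_path_factory.mktemp("bundle")
    tiny_bundle.write(outdir)
    return outdir


@pytest.fixture
def canonical_labels():
    return CANONICAL_TISSUES
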