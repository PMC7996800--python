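import numpy as np
import pytest

from cystaug.synthetic import SyntheticDatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """252-image four-class dataset (10% of the published class counts)."""
    cfg = SyntheticDatasetConfig(per_class_counts=(90, 60, 68, 34), master_seed=1)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
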