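import numpy as np
import pytest

from grassid import features as feat
from grassid import segment_plant, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A 45-plant synthetic dataset (15 per species) with the default preset."""
    return synthetic.make_dataset(n_per_species=15, seed=11)


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    plants, manifest = small_dataset
    records = [
        (pid, p.species, feat.extract_features(segment_plant(p.image)))
        for pid, p in zip(manifest["plant_id"], plants)
    ]
    return feat.feature_table(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bar_mask(height: int, width: int, pad: int = 3) -> np.ndarray:
    """A solid height×width bar embedded in a zero border."""
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad : pad + height, pad : pad + width] = True
    return m
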