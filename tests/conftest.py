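import numpy as np
import pytest

from fswolf.metrics import SplitSpec, split_dataset
from fswolf.preprocess import LabeledImageSet, standardize_image
from fswolf.synthetic import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small high-separability image set shared across tests."""
    return generate_dataset(
        SyntheticDatasetSpec(n_per_class=12, side=32, separability=1.0, seed=7)
    )


@pytest.fixture(scope="session")
def standardized_splits():
    """Standardized train/val/test splits of a small separable dataset."""
    data = generate_dataset(
        SyntheticDatasetSpec(n_per_class=20, side=32, separability=1.0, seed=3)
    )
    splits = split_dataset(data, SplitSpec(seed=3))
    out = []
    for subset in splits:
        std = [standardize_image(im, side=32) for im in subset.images]
        out.append(
            LabeledImageSet(ids=subset.ids, images=std, labels=subset.labels)
        )
    return tuple(out)
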