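import numpy as np
import pytest

from hsilesion.features import build_feature_tables
from hsilesion.phantom import PhantomConfig, generate_study_replica


@pytest.fixture(scope="session")
def study_tables():
    """Feature tables of the default 24-lesion index-mode study replica.

    Session-scoped: feature extraction over 24 lesions x 3 regions x 13
    channels is the most expensive shared step.
    """
    replica = generate_study_replica(
        n_lesions=24, mode="index", seed=11,
        config=PhantomConfig(image_size=128, seed=11),
    )
    tables, labels, lesion_ids = build_feature_tables(replica)
    return replica, tables, labels, lesion_ids


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
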