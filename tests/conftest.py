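import numpy as np
import pytest

from m6aread.classifier import train_motif_model
from m6aread.synthetic import FeatureDistribution, gen_training_set


def make_dist(motif="GGACT", separation=4.0, n_features=8, spread=1.0):
    return FeatureDistribution(
        motif=motif, n_features=n_features, separation=separation, spread=spread
    )


@pytest.fixture(scope="session")
def dist_factory():
    return make_dist


@pytest.fixture(scope="session")
def sep8_model():
    """A well-separated GGACT classifier shared across tests."""
    dist = make_dist(separation=8.0)
    X, y = gen_training_set("GGACT", 1000, dist=dist, seed=11)
    return train_motif_model(X, y, "GGACT", seed=11), dist
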