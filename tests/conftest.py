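import warnings

import numpy as np
import pytest

from hmaxbp import HmaxBayesClassifier
from hmaxbp.synthetic import build_toy_fixture, make_silhouettes


@pytest.fixture()
def toy():
    return build_toy_fixture()


# study conditions of the scaled-down end-to-end experiments: 10 object
# categories and a lighter feature budget (K_S2=100, K_C2=1000) than the
# reference configuration, one-shot training, seed 1
N_CATEGORIES = 10
SMALL_KW = dict(K_S2=100, K_C2group=10, random_state=1)
SEED = 1


@pytest.fixture(scope="session")
def silhouettes():
    return make_silhouettes(N_CATEGORIES, seed=SEED)


@pytest.fixture(scope="session")
def trained_clf(silhouettes):
    """One-shot-trained scaled-down network, shared across end-to-end
    tests (training takes a few seconds)."""
    clf = HmaxBayesClassifier(**SMALL_KW)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(np.stack(silhouettes.images), np.array(silhouettes.labels))
    return clf
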