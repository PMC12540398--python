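"""Shared fixtures.

The ``default_dataset``/``default_features`` pair is session-scoped because
full feature extraction over 9 participants x 36 trials is the expensive
step; every test that needs the full study conditions shares one pass.
"""

import numpy as np
import pytest

from mwdecode import DEFAULT_SEED, gen_dataset
from mwdecode.montage import default_montage
from mwdecode import pipeline


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_dataset():
    """3 participants x 12 trials: cheap end-to-end plumbing checks."""
    return gen_dataset(3, 12, seed=99)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 9 participants x 36 trials."""
    return gen_dataset(9, 36, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return pipeline.extract_features(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
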