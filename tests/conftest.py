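import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import scribseg as ss
from scribseg.features import make_spec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_fixture():
    """Small intensity-separable image + gt, shared across tests."""
    stack, gt = ss.make_fixture(
        ss.FixtureSpec(kind="intensity_separable", shape=(96, 96), n_classes=2,
                       noise_sd=0.05, seed=7)
    )
    return stack, gt


@pytest.fixture(scope="session")
def small_annotation(small_fixture):
    _, gt = small_fixture
    return ss.make_annotation_subset(gt, ss.ScribbleConfig(density=0.02, seed=8))


@pytest.fixture(scope="session")
def gaussian_model(small_fixture, small_annotation):
    """Cheap trained model (gaussian baseline features) on the small fixture."""
    stack, _ = small_fixture
    ts = ss.sample_training_set(stack, small_annotation, make_spec("gaussian_baseline"))
    return ss.train_classifier(ts, seed=0)


@pytest.fixture(scope="session")
def filterbank_model(small_fixture, small_annotation):
    """Filterbank model with a reduced sigma set (keeps margins small)."""
    stack, _ = small_fixture
    spec = make_spec("filterbank", sigmas=[0.7, 1.6, 3.5])
    ts = ss.sample_training_set(stack, small_annotation, spec)
    return ss.train_classifier(ts, seed=0)
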