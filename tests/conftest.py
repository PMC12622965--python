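import numpy as np
import pytest

from spnlearn.experiments import build_clustered_setup
from spnlearn.morphology import build_surrogate_morphology


@pytest.fixture(scope="session")
def morphology():
    return build_surrogate_morphology()


@pytest.fixture(scope="session")
def calibrated_model():
    """Default clustered setup (three-feature configuration), calibrated.

    Session-scoped: tests must not mutate weights without restoring them.
    """
    return build_clustered_setup(seed=0)


@pytest.fixture()
def model_weights_guard(calibrated_model):
    w = calibrated_model.w.copy()
    yield calibrated_model
    calibrated_model.w[:] = w
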