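import numpy as np
import pytest
from hypothesis import settings

import endospec as es

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return es.make_default_grid()


@pytest.fixture(scope="session")
def camera():
    return es.default_camera()


@pytest.fixture(scope="session")
def checker_target():
    """Synthetic 24-patch calibration target, seed 0."""
    return es.make_calibration_fixture(seed=0)


@pytest.fixture(scope="session")
def fitted_model(checker_target):
    return es.fit_calibration(checker_target)


@pytest.fixture(scope="session")
def exact_span_target():
    """Rank-3 target: spectra lie exactly in a 3-dim affine span."""
    return es.make_calibration_fixture(seed=0, rank=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shallow_scene():
    """One shallow + one deep vessel phantom with its masks."""
    spec = es.make_random_phantom_spec(7, size=(48, 48), n_shallow=1, n_deep=1)
    return es.make_phantom(spec)
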