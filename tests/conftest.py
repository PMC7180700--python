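import pytest

from hnphantom import FixtureParams, make_fixture


@pytest.fixture(scope="session")
def neck_params():
    return FixtureParams(seed=7)


@pytest.fixture(scope="session")
def neck(neck_params):
    """Default synthetic neck: (intensity, ground-truth labels, body mask)."""
    return make_fixture(neck_params)


@pytest.fixture(scope="session")
def small_params():
    return FixtureParams(shape=(48, 48, 24), seed=11)


@pytest.fixture(scope="session")
def small_neck(small_params):
    """Reduced-size neck for the more expensive voxel-loop oracles."""
    return make_fixture(small_params)


@pytest.fixture(scope="session")
def clean_params():
    return FixtureParams(seed=5, gaussian_sigma=0.0, salt_pepper_fraction=0.0)


@pytest.fixture(scope="session")
def clean_neck(clean_params):
    """Noise-free neck: exact-recovery baseline for clustering tests."""
    return make_fixture(clean_params)
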