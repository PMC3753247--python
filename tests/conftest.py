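import pytest

from pupilrps.synthetic_data import quiet_config, reference_fixture


@pytest.fixture(scope="session")
def fixture_set():
    """The packaged deterministic 75-game reference set (45/75 valid)."""
    return reference_fixture()


@pytest.fixture()
def quiet_cfg():
    """Noise-free, distractor-free, fixed-amplitude generator config."""
    return quiet_config()
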