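import pytest

from palmghg import calibrate_decay, make_fixture_inventory


@pytest.fixture(scope="session")
def decay_curve():
    """Decay curve calibrated to the regional forest reference stock."""
    return calibrate_decay(5.43, equilibrium_fraction=0.60, equilibrium_time=32.5)


@pytest.fixture(scope="session")
def paper_inventory():
    return make_fixture_inventory("paper_defaults")


@pytest.fixture(scope="session")
def zero_inventory():
    return make_fixture_inventory("zero_background")
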