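import pytest

from nml1 import fixtures as fx


@pytest.fixture(scope="session")
def hh_point_bundle():
    return fx.generate_fixture("hh-point-cell", seed=1)


@pytest.fixture(scope="session")
def ball_and_stick_bundle():
    return fx.generate_fixture("ball-and-stick", seed=1)


@pytest.fixture(scope="session")
def all_fixture_bundles():
    return {name: fx.generate_fixture(name, seed=1)
            for name in fx.FIXTURE_NAMES}
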