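import pytest

from cryocea.fixtures import low_risk_scenario, small_1_20mm_scenario


@pytest.fixture(scope="session")
def low_risk():
    return low_risk_scenario()


@pytest.fixture(scope="session")
def small_tumor():
    return small_1_20mm_scenario()
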