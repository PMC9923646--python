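import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from eecc_costing import CostingContext, reference_fixture


@pytest.fixture(scope="session")
def ref_model():
    return reference_fixture()


@pytest.fixture()
def ctx():
    return CostingContext()
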