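import numpy as np
import pytest
from hypothesis import settings

import beamaudit as ba

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def anchor_tables():
    return ba.load_anchor_tables()


@pytest.fixture(scope="session")
def effect_models(anchor_tables):
    return ba.build_effect_models(anchor_tables)


@pytest.fixture(scope="session")
def eclipse_community():
    """Community model over the Eclipse AAA anchor catalog."""
    return ba.default_community_config()


@pytest.fixture
def stratum():
    return ba.EquipmentStratum("Eclipse AAA", "Varian Base", "6 MV", "Millennium120")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
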