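import pytest

import oniscamp as o


@pytest.fixture(scope="session")
def matures():
    """The 18 packaged mature armadillidin peptides."""
    return o.load_mature_armadillidins()


@pytest.fixture(scope="session")
def armadillidiidae(matures):
    from oniscamp.armadillidin_char import ARMADILLIDIIDAE_IDS

    return [r for r in matures if r.id in ARMADILLIDIIDAE_IDS]


@pytest.fixture(scope="session")
def scheme():
    return o.ScoringScheme()
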