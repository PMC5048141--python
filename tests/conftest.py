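import pytest

from ampliclone.panel import default_panel
from ampliclone.simulate import ErrorModel


@pytest.fixture(scope="session")
def panel_and_mids():
    return default_panel()


@pytest.fixture(scope="session")
def panel(panel_and_mids):
    return panel_and_mids[0]


@pytest.fixture(scope="session")
def mids(panel_and_mids):
    return panel_and_mids[1]


@pytest.fixture(scope="session")
def amp(panel):
    """The KRAS exon-2 amplicon, used by most single-amplicon tests."""
    return next(a for a in panel if a.amplicon_id == "KRAS_EX2")


@pytest.fixture(scope="session")
def error_free():
    return ErrorModel.error_free()
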