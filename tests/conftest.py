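import pytest
from hypothesis import settings

from mitocomp.simulate import SimConfig, simulate_panel

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

SMALL_TREE = "((A:0.03,B:0.03):0.02,(C:0.03,D:0.03):0.02);"


@pytest.fixture(scope="session")
def panel():
    """Default 12-taxon ephemerellid-like panel."""
    return simulate_panel(SimConfig(seed=11))


@pytest.fixture(scope="session")
def panel_trni5():
    """Torleya nepalica-like panel: five tandem trnI copies."""
    return simulate_panel(SimConfig(seed=12, trni_copies=5))


@pytest.fixture(scope="session")
def small_panel():
    """4-taxon panel for cheap structural tests."""
    return simulate_panel(SimConfig(seed=13, tree=SMALL_TREE))
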