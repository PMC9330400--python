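import numpy as np
import pytest

from wgdkit.simulate import BDRates, WGDEvent, simulate_family_set
from wgdkit.trees import make_ladder_tree


@pytest.fixture(scope="session")
def ladder6():
    """The 6-taxon, 300 MY ladder used throughout the benchmark."""
    return make_ladder_tree(6, 300.0, seed=7)


@pytest.fixture(scope="session")
def ladder3():
    return make_ladder_tree(3, 100.0, seed=1)


@pytest.fixture(scope="session")
def planted_families(ladder6):
    """2,000 families with a WGD (retention 0.2) at the midpoint above N3."""
    fams, rejected = simulate_family_set(
        ladder6,
        BDRates(0.002, 0.002),
        [WGDEvent("N3", retention_rate=0.2, event_id="WGD1")],
        2000,
        seed=11,
    )
    return fams


@pytest.fixture(scope="session")
def neutral_families(ladder6):
    """2,000 families under the pure birth-death null (no WGD)."""
    fams, rejected = simulate_family_set(
        ladder6, BDRates(0.002, 0.002), [], 2000, seed=23
    )
    return fams


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
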