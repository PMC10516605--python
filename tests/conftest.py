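import numpy as np
import pytest

from msikit.panel import default_panel, make_locus_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel(seed=0)


@pytest.fixture(scope="session")
def locus_a24(panel):
    return next(loc for loc in panel if loc.locus_id == "mU12235-A24")


@pytest.fixture(scope="session")
def coding_locus(panel):
    return next(loc for loc in panel if loc.locus_id == "Asxl1")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_panel():
    """Two short loci for fast read-level tests."""
    return make_locus_panel(
        [
            {"locus_id": "locA", "repeat_unit": "A", "wt_repeat_count": 12},
            {"locus_id": "locB", "repeat_unit": "T", "wt_repeat_count": 9},
        ],
        seed=11,
    )
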