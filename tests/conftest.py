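import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from cystrace import (
    DEFAULT_FRAGMENTS,
    DEFAULT_ISOTOPES,
    ChemicalFormula,
    FragmentDefinition,
    monoisotopic_table,
)


@pytest.fixture(scope="session")
def isotope_table():
    return DEFAULT_ISOTOPES


@pytest.fixture(scope="session")
def mono_table():
    return monoisotopic_table()


@pytest.fixture(scope="session")
def default_fragments():
    return DEFAULT_FRAGMENTS


@pytest.fixture
def c1_fragment():
    """Single-carbon fragment with one tracked backbone carbon and one shift."""
    return FragmentDefinition(
        metabolite="toy",
        fragment_name="c1",
        fragment_formula=ChemicalFormula({"C": 1}),
        n_backbone_carbons=1,
        n_measured_shifts=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
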