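import numpy as np
import pytest

from ocscreen.featurization import SmartsCatalog
from ocscreen.synthetic import SyntheticConfig, generate_compound_library


@pytest.fixture(scope="session")
def mini_catalog() -> SmartsCatalog:
    """Three-pattern catalog (hydroxyl, carbonyl, aromatic ring)."""
    return SmartsCatalog.from_pairs([
        ("hydroxyl", "[OX2H]"),
        ("carbonyl", "[CX3]=[OX1]"),
        ("aromatic_ring", "c1ccccc1"),
    ])


@pytest.fixture(scope="session")
def small_library():
    """200 fragment-assembled compounds with exact ground-truth features."""
    return generate_compound_library(SyntheticConfig(seed=11, n_compounds=200))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
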