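import numpy as np
import pytest

from ssefold.fixtures import FixtureSpec, build_toy_rna
from ssefold.library import build_library
from ssefold.pair_annotation import derive_secondary_structure

HAIRPIN_SEQ = "GGGGAAAACCCC"
HAIRPIN_SS = "((((....))))"


@pytest.fixture
def hairpin_chain():
    chain, _ = build_toy_rna(FixtureSpec(HAIRPIN_SEQ, HAIRPIN_SS), source_id="HP1")
    derive_secondary_structure(chain)
    return chain


@pytest.fixture
def hairpin_library(hairpin_chain):
    return build_library([hairpin_chain], "lib1")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
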