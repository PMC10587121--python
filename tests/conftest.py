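import itertools

import pytest

from ddscreen.library_design import (
    SYNTHETIC_LOCUS_SPACERS,
    build_library,
)


def brute_force_triplets() -> set[str]:
    """Independent oracle: every 3-mer with >=1 C, except CCC."""
    return {
        "".join(t)
        for t in itertools.product("ACGT", repeat=3)
        if "C" in t and "".join(t) != "CCC"
    }


@pytest.fixture(scope="session")
def library():
    """The full 38-member library (36 triplet spacers + 2 locus stand-ins)."""
    return build_library(locus_spacers=SYNTHETIC_LOCUS_SPACERS, seed=11)


@pytest.fixture(scope="session")
def triplet_library():
    """The 36-triplet library without locus spacers."""
    return build_library(seed=11)
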