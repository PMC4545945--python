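import numpy as np
import pytest

from ssrkit import GenotypeTable


def random_dna(rng: np.random.Generator, length: int,
               p=(0.3, 0.2, 0.2, 0.3)) -> str:
    """AT-biased random DNA, the composition of a plant genome survey."""
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150819)


@pytest.fixture
def small_table() -> GenotypeTable:
    """Four accessions x three loci with one missing call, hand-built."""
    calls = {
        "L1": {"a1": ("A", "A"), "a2": ("A", "B"), "a3": ("B", "B"), "a4": ("A", "A")},
        "L2": {"a1": ("B", "C"), "a2": ("B", "C"), "a3": ("C", "C"), "a4": None},
        "L3": {"a1": ("X", "X"), "a2": ("X", "X"), "a3": ("X", "X"), "a4": ("X", "X")},
    }
    return GenotypeTable(loci=["L1", "L2", "L3"],
                         accessions=["a1", "a2", "a3", "a4"], calls=calls)
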