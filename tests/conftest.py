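import numpy as np
import pytest

from sortscreen import SgRNAElement, SgRNALibrary
from sortscreen.simulate import random_library


def make_protospacer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_library() -> SgRNALibrary:
    """3 genes x 2 guides + 3 NTCs, fixed protospacers."""
    elements = [
        SgRNAElement("G1_sg1", "AAAACCCCGGGGTTTTAAAA", "G1"),
        SgRNAElement("G1_sg2", "CCCCGGGGTTTTAAAACCCC", "G1"),
        SgRNAElement("G2_sg1", "GGGGTTTTAAAACCCCGGGG", "G2"),
        SgRNAElement("G2_sg2", "TTTTAAAACCCCGGGGTTTT", "G2"),
        SgRNAElement("G3_sg1", "ACGTACGTACGTACGTACGT", "G3"),
        SgRNAElement("G3_sg2", "TGCATGCATGCATGCATGCA", "G3"),
        SgRNAElement("NTC_sg1", "AATTCCGGAATTCCGGAATT", "NTC", is_ntc=True),
        SgRNAElement("NTC_sg2", "CCGGAATTCCGGAATTCCGG", "NTC", is_ntc=True),
        SgRNAElement("NTC_sg3", "GGAATTCCGGAATTCCGGAA", "NTC", is_ntc=True),
    ]
    return SgRNALibrary(elements=tuple(elements), name="tiny")


@pytest.fixture
def medium_library() -> SgRNALibrary:
    """Randomized 20-gene library for property-style checks."""
    return random_library(n_genes=20, sgrnas_per_gene=5, n_ntc=30, seed=42)
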