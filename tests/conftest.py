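import numpy as np
import pytest

from norascan.align import CodonAlignment
from norascan.ancestral import AncestralSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(rows: dict[str, list[str]], gene: str = "g") -> CodonAlignment:
    return CodonAlignment(gene, {k: list(v) for k, v in rows.items()})


def ancestor_from_codons(codons) -> AncestralSequence:
    """Wrap a known codon sequence as an AncestralSequence (support 1)."""
    states = "".join(codons)
    return AncestralSequence(states, np.ones(len(states)))


@pytest.fixture
def make_aln():
    return make_alignment


@pytest.fixture
def as_ancestor():
    return ancestor_from_codons
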