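import numpy as np
import pytest

from nlrkit.io import Alignment, AnnotationSet, Feature, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_seq_alignment():
    """The hand-enumerable 3-haplotype example: pi_total = 4/3, S = 2."""
    return Alignment(
        [
            SequenceRecord("a", "AAAAA"),
            SequenceRecord("b", "AAAAT"),
            SequenceRecord("c", "AATAT"),
        ],
        alphabet="nucleotide",
    )


@pytest.fixture
def toy_genes():
    return AnnotationSet(
        [
            Feature("Chr1", 1001, 2000, "+", "gene", "g1"),
            Feature("Chr1", 5000, 6000, "-", "gene", "g2"),
        ]
    )
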