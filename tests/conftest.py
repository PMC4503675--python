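import numpy as np
import pytest

from lncorf.sequence_features import CodingSequence


@pytest.fixture
def toy_orf() -> CodingSequence:
    """Minimal ORF with one fragile codon (TGG) and its terminal stop."""
    return CodingSequence("toy", "human", "ATGTGGTAA",
                          includes_terminal_stop=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_orf(n_codons: int, gc: float, seed: int) -> CodingSequence:
    """Random valid ORF including terminal stop."""
    from lncorf.synthetic_data import SequenceSimConfig, generate_coding_sequence

    return generate_coding_sequence(
        SequenceSimConfig(length=3 * n_codons, gc_target=gc, ensure_orf=True,
                          seed=seed)
    )
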