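import numpy as np
import pytest

from epialign import CompressedSequence, StateAlphabet


@pytest.fixture(scope="session")
def alpha15() -> StateAlphabet:
    return StateAlphabet.roadmap15()


@pytest.fixture(scope="session")
def alpha4() -> StateAlphabet:
    return StateAlphabet.from_size(4)


def seq_from_letters(text: str, alphabet: StateAlphabet, runs=None) -> CompressedSequence:
    """Compressed sequence from a letter string (unit runs unless given)."""
    states = np.array([alphabet.state_of_letter(ch) for ch in text], dtype=np.int64)
    if runs is None:
        runs = np.ones(states.size, dtype=np.int64)
    return CompressedSequence(states, np.asarray(runs), alphabet=alphabet)


def random_compressed(rng, n, q, alphabet=None) -> CompressedSequence:
    """Random valid compressed sequence: i.i.d. states conditioned on no repeat."""
    states = [int(rng.integers(1, q + 1))]
    while len(states) < n:
        c = int(rng.integers(1, q + 1))
        if c != states[-1]:
            states.append(c)
    return CompressedSequence(
        np.array(states, dtype=np.int64),
        np.ones(n, dtype=np.int64),
        alphabet=alphabet,
    )
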