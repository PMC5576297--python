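import numpy as np
import pytest

from pssmrt.pssm import (
    NormalizedPssm,
    ProteinChain,
    Pssm,
    ResidueInstance,
    extract_window,
    normalize,
)


def make_instance(window: np.ndarray, residues: str | None = None, pad=None) -> ResidueInstance:
    """Build a residue instance directly from a w x 20 matrix."""
    w = window.shape[0]
    if pad is None:
        pad = np.zeros(w, dtype=bool)
    if residues is None:
        residues = "A" * w
    return ResidueInstance("test", (w + 1) // 2, w, np.asarray(window, float), np.asarray(pad), residues)


def uniform_instance(w: int, c: float) -> ResidueInstance:
    """Unpadded instance whose normalised window is constant c."""
    return make_instance(np.full((w, 20), c))


def random_instance(rng: np.random.Generator, w: int) -> ResidueInstance:
    """Unpadded instance from a random integer PSSM of length >= w."""
    L = w + int(rng.integers(0, 10))
    scores = rng.integers(-10, 11, size=(L, 20))
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), L))
    npssm = normalize(Pssm("rand", scores, seq))
    i = int(rng.integers(1, L + 1))
    return extract_window(npssm, i, w, ProteinChain("rand", seq))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_chain():
    return ProteinChain("toy_A", "MKRLS")


@pytest.fixture
def toy_pssm(toy_chain):
    scores = np.zeros((5, 20), dtype=int)
    scores[0, 0] = 5  # row 1, column A
    return Pssm(toy_chain.chain_id, scores, toy_chain.sequence)
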