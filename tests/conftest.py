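"""Shared fixtures: toy molecules and a dense Pauli/statevector oracle.

The statevector oracle is deliberately independent of the package's
symbolic ladder algebra: Pauli strings are built by Kronecker products of
explicit 2x2 matrices, and fermionic expectations by applying sparse
Jordan-Wigner annihilation operators to the state.
"""

import numpy as np
import pytest

from rdmcomplete.fixtures import (
    _annihilators,
    _build_hamiltonian,
    _sector_indices,
    toy_molecule_fixtures,
)

_I = np.eye(2)
_X = np.array([[0.0, 1.0], [1.0, 0.0]])
_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]])
_Z = np.diag([1.0, -1.0])
_PAULI = {"I": _I, "X": _X, "Y": _Y, "Z": _Z}


def dense_pauli(letters: str) -> np.ndarray:
    m = np.eye(1)
    for c in letters:
        m = np.kron(m, _PAULI[c])
    return m


def pauli_expectation_dense(letters: str, psi: np.ndarray) -> float:
    return float(np.real(psi.conj() @ (dense_pauli(letters) @ psi)))


def fermionic_expectation_dense(i: int, k: int, l: int, j: int,
                                psi: np.ndarray, n_so: int) -> float:
    """<a†_i a†_k a_l a_j> by direct operator application."""
    ann = _annihilators(n_so)
    bra = ann[k] @ (ann[i] @ psi)
    ket = ann[l] @ (ann[j] @ psi)
    return float(bra @ ket)


def ground_state(ints, n_alpha: int, n_beta: int) -> np.ndarray:
    """Lowest eigenvector of the toy Hamiltonian in its number sector."""
    n_so = 2 * ints.n_orb
    h = _build_hamiltonian(ints, n_so)
    idx = _sector_indices(n_so, n_alpha, n_beta)
    hs = h[np.ix_(idx, idx)].toarray()
    _, v = np.linalg.eigh(hs)
    psi = np.zeros(2 ** n_so)
    psi[idx] = v[:, 0]
    return psi


@pytest.fixture(scope="session")
def pair_n3():
    return toy_molecule_fixtures("pair_n3")


@pytest.fixture(scope="session")
def beh_like():
    return toy_molecule_fixtures("beh_like")


@pytest.fixture(scope="session")
def closed_shell():
    return toy_molecule_fixtures("closed_shell")


@pytest.fixture(scope="session")
def lih_like():
    return toy_molecule_fixtures("lih_like")
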