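"""Data model for fermionic one- and two-particle reduced density matrices.

The two-particle reduced density matrix (2-RDM) of an electronic system,

    P_ik,jl = <a†_i a†_k a_l a_j>,

determines the energy of any two-body Hamiltonian.  In a real-orbital basis
with a good Sz quantum number the 2-RDM has only three unique nonzero spin
sectors — aaaa, bbbb and abab — and an 8-fold permutational symmetry within
the same-spin sectors.  Each sector is stored here as a symmetric ``d x d``
matrix over composite pair indices:

* same-spin sectors keep one representative per symmetry orbit, the strictly
  ordered pairs ``i > k``, ``j > l``, giving ``d = n(n-1)/2``;
* the abab sector has only the 2-fold symmetry ``P_ik,jl = P_jl,ik`` and is
  stored over all ``n^2`` ordered pairs.

This module provides the packed containers, the pack/unpack codec with the
sign rule, the Hartree-Fock product construction, contraction to the 1-RDM,
the energy functional, and spectral/rank utilities used by rank selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAME_SPIN_SECTORS",
    "SECTORS",
    "PackedSectorMatrix",
    "TwoRDM",
    "OneRDM",
    "MolecularIntegrals",
    "same_spin_pairs",
    "same_spin_dim",
    "abab_dim",
    "sector_dim",
    "pack_sector",
    "unpack_sector",
    "hartree_fock_2rdm",
    "contract_to_1rdm",
    "energy",
    "singular_spectrum",
    "rank_truncation_error",
    "hf_minimum_ranks",
    "sector_trace_targets",
    "count_unique_spin_sectors",
]

SAME_SPIN_SECTORS = ("aaaa", "bbbb")
SECTORS = ("aaaa", "bbbb", "abab")

_SYM_TOL = 1e-12


# ---------------------------------------------------------------------------
# pair-index bookkeeping
# ---------------------------------------------------------------------------

def same_spin_pairs(n: int) -> list[tuple[int, int]]:
    """Strictly ordered orbital pairs ``(i, k)`` with ``i > k``.

    The composite index of ``(i, k)`` is ``i(i-1)/2 + k`` (0-based,
    lexicographic), so ``pairs[a]`` inverts the map.
    """
    return [(i, k) for i in range(n) for k in range(i)]


def same_spin_dim(n: int) -> int:
    return n * (n - 1) // 2


def abab_dim(n: int) -> int:
    return n * n


def sector_dim(sector_label: str, n: int) -> int:
    if sector_label in SAME_SPIN_SECTORS:
        return same_spin_dim(n)
    if sector_label == "abab":
        return abab_dim(n)
    raise ValueError(f"unknown sector label {sector_label!r}")


def _pair_index_same(i: int, k: int) -> int:
    # caller guarantees i > k
    return i * (i - 1) // 2 + k


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PackedSectorMatrix:
    """One spin sector of a 2-RDM as a symmetric matrix over pair indices."""

    sector_label: str
    n_orb: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sector_label not in SECTORS:
            raise ValueError(f"unknown sector label {self.sector_label!r}")
        self.values = np.asarray(self.values, dtype=float)
        d = sector_dim(self.sector_label, self.n_orb)
        if self.values.shape != (d, d):
            raise ValueError(
                f"sector {self.sector_label}: expected shape {(d, d)}, "
                f"got {self.values.shape}"
            )
        scale = max(np.abs(self.values).max(), 1.0)
        if not np.allclose(self.values, self.values.T,
                           rtol=_SYM_TOL, atol=_SYM_TOL * scale):
            raise ValueError(
                f"sector {self.sector_label}: packed matrix is not symmetric"
            )
        # store the exactly symmetrized representative
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def d(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "PackedSectorMatrix":
        return PackedSectorMatrix(self.sector_label, self.n_orb,
                                  self.values.copy())


@dataclass
class TwoRDM:
    """A 2-RDM as its unique spin sectors plus electron/orbital bookkeeping.

    ``sectors`` maps sector labels to :class:`PackedSectorMatrix` over the
    *active* orbitals; ``frozen_core`` records how many low-lying spatial
    orbitals were folded out (their contribution enters the energy through
    the integrals' core constant, never through these sectors).
    """

    sectors: dict[str, PackedSectorMatrix]
    n_orb: int
    n_alpha: int
    n_beta: int
    frozen_core: int = 0

    def __post_init__(self) -> None:
        if "abab" not in self.sectors:
            raise ValueError("abab sector must always be present")
        if self.n_alpha >= 2 and "aaaa" not in self.sectors:
            raise ValueError("aaaa sector required when n_alpha >= 2")
        if self.n_beta >= 2 and "bbbb" not in self.sectors:
            raise ValueError("bbbb sector required when n_beta >= 2")
        for label, sec in self.sectors.items():
            if sec.sector_label != label:
                raise ValueError(f"sector stored under wrong label {label!r}")
            if sec.n_orb != self.n_orb:
                raise ValueError("sector orbital count mismatch")

    @property
    def n_el(self) -> int:
        return self.n_alpha + self.n_beta

    def copy(self) -> "TwoRDM":
        return TwoRDM({k: v.copy() for k, v in self.sectors.items()},
                      self.n_orb, self.n_alpha, self.n_beta, self.frozen_core)


@dataclass
class OneRDM:
    d_alpha: np.ndarray
    d_beta: np.ndarray

    def __post_init__(self) -> None:
        self.d_alpha = np.asarray(self.d_alpha, dtype=float)
        self.d_beta = np.asarray(self.d_beta, dtype=float)

    @property
    def trace(self) -> float:
        return float(np.trace(self.d_alpha) + np.trace(self.d_beta))


@dataclass
class MolecularIntegrals:
    """One- and two-electron integrals of the active space, in Hartree.

    ``v[i, k, j, l]`` is the physicists'-notation integral <ik|jl>, paired
    with ``P_ik,jl`` in the energy functional.  ``e_core`` carries the
    nuclear repulsion plus any frozen-core contribution.
    """

    t: np.ndarray
    v: np.ndarray
    e_core: float = 0.0
    n_orb: int = field(default=0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = self.t.shape[0]
        if self.n_orb == 0:
            self.n_orb = n
        if self.t.shape != (n, n) or self.n_orb != n:
            raise ValueError("t must be n x n matching n_orb")
        if self.v.shape != (n, n, n, n):
            raise ValueError("v must be a 4-index n^4 tensor")
        if not np.allclose(self.t, self.t.T, atol=1e-10):
            raise ValueError("t must be symmetric")
        # real-orbital 8-fold symmetry of <ik|jl>: i<->j, k<->l, (ik)<->(kl) swap
        for perm in [(2, 1, 0, 3), (0, 3, 2, 1), (1, 0, 3, 2)]:
            if not np.allclose(self.v, self.v.transpose(perm), atol=1e-10):
                raise ValueError("v violates real-orbital integral symmetry")


# ---------------------------------------------------------------------------
# pack / unpack codec
# ---------------------------------------------------------------------------

def _check_same_spin_symmetry(t: np.ndarray, tol: float) -> None:
    """Validate the 8-fold pattern of a same-spin sector tensor.

    P_ik,jl = -P_ki,jl = -P_ik,lj = P_ki,lj = P_jl,ik (and compositions).
    Raises with an offending index quadruple.
    """
    scale = max(np.abs(t).max(), 1.0)
    checks = [
        ((1, 0, 2, 3), -1.0, "antisymmetry in (i,k)"),
        ((0, 1, 3, 2), -1.0, "antisymmetry in (j,l)"),
        ((2, 3, 0, 1), +1.0, "pair-exchange symmetry"),
    ]
    for perm, sign, what in checks:
        diff = np.abs(t - sign * t.transpose(perm))
        if diff.max() > tol * scale:
            idx = np.unravel_index(int(np.argmax(diff)), t.shape)
            raise ValueError(
                f"same-spin tensor violates {what} at indices {idx} "
                f"(deviation {diff.max():.3e})"
            )


def _check_abab_symmetry(t: np.ndarray, tol: float) -> None:
    scale = max(np.abs(t).max(), 1.0)
    diff = np.abs(t - t.transpose(2, 3, 0, 1))
    if diff.max() > tol * scale:
        idx = np.unravel_index(int(np.argmax(diff)), t.shape)
        raise ValueError(
            f"abab tensor violates pair-exchange symmetry at {idx} "
            f"(deviation {diff.max():.3e})"
        )


def pack_sector(tensor: np.ndarray, sector_label: str,
                tol: float = 1e-10) -> PackedSectorMatrix:
    """Pack a 4-index sector tensor into its symmetric pair-index matrix.

    The tensor is validated against the permutational symmetry of its sector;
    one representative per symmetry orbit is stored (``i > k``, ``j > l`` for
    same-spin sectors, all ordered pairs for abab).
    """
    t = np.asarray(tensor, dtype=float)
    n = t.shape[0]
    if t.shape != (n, n, n, n):
        raise ValueError("sector tensor must be 4-index with equal dims")
    if sector_label in SAME_SPIN_SECTORS:
        _check_same_spin_symmetry(t, tol)
        pairs = same_spin_pairs(n)
        d = len(pairs)
        m = np.empty((d, d))
        for a, (i, k) in enumerate(pairs):
            for b, (j, l) in enumerate(pairs):
                m[a, b] = t[i, k, j, l]
    else:
        _check_abab_symmetry(t, tol)
        m = t.reshape(n * n, n * n)
    return PackedSectorMatrix(sector_label, n, 0.5 * (m + m.T))


def unpack_sector(packed: PackedSectorMatrix) -> np.ndarray:
    """Regenerate the full 4-index sector tensor with the 8-fold sign rule."""
    n = packed.n_orb
    if packed.sector_label in SAME_SPIN_SECTORS:
        pairs = same_spin_pairs(n)
        t = np.zeros((n, n, n, n))
        for a, (i, k) in enumerate(pairs):
            for b, (j, l) in enumerate(pairs):
                v = packed.values[a, b]
                t[i, k, j, l] = v
                t[k, i, j, l] = -v
                t[i, k, l, j] = -v
                t[k, i, l, j] = v
        return t
    return packed.values.reshape(n, n, n, n).copy()


# ---------------------------------------------------------------------------
# Hartree-Fock construction and contraction
# ---------------------------------------------------------------------------

def hartree_fock_2rdm(d_alpha: np.ndarray, d_beta: np.ndarray,
                      idem_tol: float = 1e-8) -> TwoRDM:
    """Build the mean-field 2-RDM from idempotent spin 1-RDMs.

    Same-spin sectors follow the product form
    ``P_ik,jl = D_ij D_kl - D_il D_kj`` and the opposite-spin sector is
    ``P_ik,jl = D^a_ij D^b_kl``.  The resulting sector ranks are the minimum
    ranks of an electronic system: Ns(Ns-1)/2 same-spin and Na*Nb for abab.
    """
    da = np.asarray(d_alpha, dtype=float)
    db = np.asarray(d_beta, dtype=float)
    n = da.shape[0]
    for name, d in (("alpha", da), ("beta", db)):
        if np.abs(d @ d - d).max() > idem_tol:
            warnings.warn(f"{name} 1-RDM is not idempotent; "
                          "product 2-RDM is not a pure-state mean-field RDM",
                          stacklevel=2)
    n_alpha = int(round(np.trace(da)))
    n_beta = int(round(np.trace(db)))
    sectors: dict[str, PackedSectorMatrix] = {}
    same = (np.einsum("ij,kl->ikjl", da, da)
            - np.einsum("il,kj->ikjl", da, da))
    sectors["aaaa"] = pack_sector(same, "aaaa")
    same_b = (np.einsum("ij,kl->ikjl", db, db)
              - np.einsum("il,kj->ikjl", db, db))
    sectors["bbbb"] = pack_sector(same_b, "bbbb")
    sectors["abab"] = pack_sector(np.einsum("ij,kl->ikjl", da, db), "abab")
    if n_alpha < 2:
        del sectors["aaaa"]
    if n_beta < 2:
        del sectors["bbbb"]
    return TwoRDM(sectors, n, n_alpha, n_beta)


def contract_to_1rdm(rdm2: TwoRDM) -> OneRDM:
    """Contract the 2-RDM down to the 1-RDM.

    Over spin orbitals, ``sum_k P_ik,jk = (N_el - 1) D_ij``; resolved into
    spin blocks the alpha block receives the aaaa and abab sectors and the
    beta block the bbbb sector plus abab with its alpha index traced.
    """
    n_el = rdm2.n_el
    if n_el < 2:
        raise ValueError("contraction requires at least two electrons")
    n = rdm2.n_orb
    d_a = np.zeros((n, n))
    d_b = np.zeros((n, n))
    if "aaaa" in rdm2.sectors:
        t = unpack_sector(rdm2.sectors["aaaa"])
        d_a += np.einsum("ikjk->ij", t)
    if "bbbb" in rdm2.sectors:
        t = unpack_sector(rdm2.sectors["bbbb"])
        d_b += np.einsum("ikjk->ij", t)
    tab = unpack_sector(rdm2.sectors["abab"])
    d_a += np.einsum("ikjk->ij", tab)
    d_b += np.einsum("kikj->ij", tab)
    return OneRDM(d_a / (n_el - 1), d_b / (n_el - 1))


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def energy(rdm2: TwoRDM, ints: MolecularIntegrals) -> tuple[float, float]:
    """Total electronic energy and its two-particle part E2.

    ``E2 = 1/2 sum_{spin orbitals} V_ikjl P_ik,jl`` reconstructed from the
    spin sectors (the abab sector enters twice, once per spin ordering);
    ``E_total = sum t_ij D_ij + E2 + e_core`` with D from contraction.
    Both cover the active (non-core) space only.
    """
    if rdm2.n_orb != ints.n_orb:
        raise ValueError(
            f"active-space mismatch: rdm2 has {rdm2.n_orb} orbitals, "
            f"integrals have {ints.n_orb}"
        )
    v = ints.v
    e2 = 0.0
    for label in SAME_SPIN_SECTORS:
        if label in rdm2.sectors:
            e2 += 0.5 * np.einsum(
                "ikjl,ikjl->", v, unpack_sector(rdm2.sectors[label]))
    e2 += np.einsum("ikjl,ikjl->", v, unpack_sector(rdm2.sectors["abab"]))
    d1 = contract_to_1rdm(rdm2)
    e1 = float(np.einsum("ij,ij->", ints.t, d1.d_alpha + d1.d_beta))
    return e1 + e2 + ints.e_core, float(e2)


# ---------------------------------------------------------------------------
# spectra, ranks, traces
# ---------------------------------------------------------------------------

def singular_spectrum(m: PackedSectorMatrix | np.ndarray) -> np.ndarray:
    """Singular values of a packed sector matrix, descending."""
    a = m.values if isinstance(m, PackedSectorMatrix) else np.asarray(m)
    return np.linalg.svd(a, compute_uv=False)


def rank_truncation_error(spectrum: np.ndarray, r: int) -> float:
    """Relative Frobenius error of the best rank-``r`` approximation.

    ``eps_trunc = sqrt(sum_{i>r} s_i^2) / sqrt(sum_i s_i^2)`` for the
    descending singular values ``s``; 1 at r=0, 0 at full rank.
    """
    s = np.asarray(spectrum, dtype=float)
    d = s.size
    if not 0 <= r <= d:
        raise ValueError(f"rank {r} outside [0, {d}]")
    total = float(np.sum(s ** 2))
    if total == 0.0:
        return 0.0
    return float(np.sqrt(np.sum(s[r:] ** 2) / total))


def hf_minimum_ranks(n_alpha: int, n_beta: int) -> dict[str, int]:
    """Sector ranks of the mean-field 2-RDM — the electronic minimum ranks."""
    if n_alpha < 0 or n_beta < 0:
        raise ValueError("electron counts must be nonnegative")
    return {
        "aaaa": n_alpha * (n_alpha - 1) // 2,
        "bbbb": n_beta * (n_beta - 1) // 2,
        "abab": n_alpha * n_beta,
    }


def sector_trace_targets(n_alpha: int, n_beta: int) -> dict[str, float]:
    """Exact packed-matrix traces of each sector for given electron counts.

    Under the strict-pair packing the same-spin trace is
    ``sum_{i>k} P_ik,ik = Ns(Ns-1)/2`` and the abab trace is ``Na*Nb``;
    these are the targets of trace-normalization postprocessing.
    """
    if n_alpha < 0 or n_beta < 0:
        raise ValueError("electron counts must be nonnegative")
    return {
        "aaaa": n_alpha * (n_alpha - 1) / 2.0,
        "bbbb": n_beta * (n_beta - 1) / 2.0,
        "abab": float(n_alpha * n_beta),
    }


def count_unique_spin_sectors(rdm2: TwoRDM, tol: float = 1e-10) -> int:
    """Number of nonzero spin-sector blocks unique under permutational symmetry.

    Enumerates all 16 spin-label combinations (s1 s2, s3 s4) of
    ``P_{i s1, k s2, j s3, l s4}``, reduces them by the 8-fold permutational
    symmetry (which maps a sector to itself or to a partner sector, e.g.
    abab ~ baba ~ abba ~ baab), and counts the equivalence classes whose
    block has Frobenius norm above ``tol``.  For an Sz eigenstate this is 3
    when both same-spin sectors are populated.
    """
    n = rdm2.n_orb
    full = {}  # (s1,s2,s3,s4) -> 4-index block over spatial orbitals
    zero = np.zeros((n, n, n, n))
    for s1 in "ab":
        for s2 in "ab":
            for s3 in "ab":
                for s4 in "ab":
                    full[(s1, s2, s3, s4)] = zero
    if "aaaa" in rdm2.sectors:
        full[("a", "a", "a", "a")] = unpack_sector(rdm2.sectors["aaaa"])
    if "bbbb" in rdm2.sectors:
        full[("b", "b", "b", "b")] = unpack_sector(rdm2.sectors["bbbb"])
    tab = unpack_sector(rdm2.sectors["abab"])
    full[("a", "b", "a", "b")] = tab
    full[("b", "a", "b", "a")] = tab.transpose(1, 0, 3, 2)
    full[("a", "b", "b", "a")] = -tab.transpose(0, 1, 3, 2)
    full[("b", "a", "a", "b")] = -tab.transpose(1, 0, 2, 3)

    # orbit of a sector label under the permutational symmetry group
    def orbit(labels: tuple[str, str, str, str]) -> frozenset:
        s1, s2, s3, s4 = labels
        return frozenset([
            (s1, s2, s3, s4), (s2, s1, s4, s3),
            (s1, s2, s4, s3), (s2, s1, s3, s4),
            (s3, s4, s1, s2), (s4, s3, s2, s1),
            (s3, s4, s2, s1), (s4, s3, s1, s2),
        ])

    seen: set[frozenset] = set()
    count = 0
    for labels, block in full.items():
        orb = orbit(labels)
        if orb in seen:
            continue
        seen.add(orb)
        if np.linalg.norm(block) > tol:
            count += 1
    return count
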