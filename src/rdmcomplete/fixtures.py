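"""Synthetic inputs with the statistical structure the completion method assumes.

Two families of fixtures are provided, so that every stage of the pipeline
can be exercised without external quantum-chemistry software:

* **Synthetic spectra** — approximately low-rank symmetric PSD matrices
  ``M = U L U^T`` with a prescribed head rank, an exponentially decaying
  tail (the spectral shape of correlated 2-RDMs), and a coherence knob that
  interpolates the eigenvectors between Haar-random (incoherent, mu ~ 1)
  and axis-aligned (maximally coherent, mu = d/r).

* **Toy molecules** — small hard-coded model Hamiltonians (one- and
  two-electron integrals built from a seeded, 8-fold-symmetric, positive
  two-electron kernel) solved by a self-contained electronic-structure
  engine: unrestricted Hartree-Fock, optional frozen-core folding, exact
  diagonalization in the particle-number sector for the correlated *target*
  2-RDM, and a first-order perturbative wavefunction (Epstein-Nesbet
  partitioning) for the cheap *model* 2-RDM, mirroring the MP2-model /
  coupled-cluster-target relationship the protocol is designed around.
  These are synthetic few-electron systems, not real molecules.

An adapter contract (:class:`ElectronicStructureBackend`) documents how a
user can plug in a real backend to produce MP2/CCSD RDMs; nothing in this
package requires one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Protocol

import numpy as np
import scipy.sparse as sp

from .rdm_model import (
    MolecularIntegrals,
    OneRDM,
    PackedSectorMatrix,
    TwoRDM,
    pack_sector,
    sector_dim,
)

__all__ = [
    "SyntheticSpec",
    "synth_psd",
    "synth_psd_matrix",
    "synth_model_target_pair",
    "synth_two_rdm",
    "ToyFixture",
    "toy_molecule_fixtures",
    "toy_presets",
    "ElectronicStructureBackend",
]


# ---------------------------------------------------------------------------
# synthetic PSD matrices with controlled spectrum and coherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for an approximately rank-``r`` symmetric PSD matrix.

    ``decay`` is the exponential log-slope of the tail singular values
    beyond the head rank (``decay = 0`` means no tail: exactly rank ``r``).
    ``coherence`` in [0, 1] moves the eigenvectors from Haar-random (0)
    to axis-aligned (1).  ``perturbation`` sets the relative scale of the
    model/target mismatch in :func:`synth_model_target_pair`.
    """

    d: int
    rank: int
    decay: float = 1.0
    coherence: float = 0.0
    perturbation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.d:
            raise ValueError("rank must lie in [1, d]")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence knob must lie in [0, 1]")
        if self.decay < 0 or self.perturbation < 0:
            raise ValueError("decay and perturbation must be nonnegative")


def _spectrum(spec: SyntheticSpec) -> np.ndarray:
    """Head values 1/(1+i) for i < r, exponential tail below the head."""
    lam = np.zeros(spec.d)
    head = 1.0 / (1.0 + np.arange(spec.rank))
    lam[:spec.rank] = head
    if spec.decay > 0 and spec.rank < spec.d:
        tail_len = spec.d - spec.rank
        lam[spec.rank:] = head[-1] * np.exp(
            -spec.decay * np.arange(1, tail_len + 1))
    return lam


def _coherent_basis(d: int, coherence: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Orthogonal basis between Haar-random and the identity.

    Built from a stream of random Givens rotations applied to the identity;
    the coherence knob is the fraction of rotations skipped, so 1 leaves
    the axis-aligned identity and 0 applies the full stream (approximately
    Haar for the leverage statistics that matter here).
    """
    n_full = 6 * d * d
    n_apply = int(round((1.0 - coherence) * n_full))
    u = np.eye(d)
    for _ in range(n_apply):
        i, j = rng.choice(d, size=2, replace=False)
        th = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(th), np.sin(th)
        ui, uj = u[i].copy(), u[j].copy()
        u[i] = c * ui - s * uj
        u[j] = s * ui + c * uj
    return u.T


def synth_psd_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Symmetric PSD matrix with the spectrum and coherence of ``spec``."""
    rng = np.random.default_rng(spec.seed)
    lam = _spectrum(spec)
    u = _coherent_basis(spec.d, spec.coherence, rng)
    return (u * lam) @ u.T


def synth_psd(spec: SyntheticSpec,
              sector_label: str = "abab") -> PackedSectorMatrix:
    """Wrap a synthetic PSD matrix as a packed 2-RDM sector.

    ``spec.d`` must match the packed dimension of the sector for some
    orbital count (``n^2`` for abab, ``n(n-1)/2`` for same-spin sectors).
    """
    m = synth_psd_matrix(spec)
    for n in range(1, spec.d + 2):
        if sector_dim(sector_label, n) == spec.d:
            return PackedSectorMatrix(sector_label, n, m)
    raise ValueError(
        f"d={spec.d} is not a valid packed dimension for {sector_label}")


def synth_model_target_pair(spec: SyntheticSpec
                            ) -> tuple[np.ndarray, np.ndarray]:
    """A (model, target) pair differing by a PSD low-rank perturbation.

    ``target = model + E`` with ``E`` PSD of rank ``min(2r, d)`` scaled so
    that ``||E||_F = perturbation * ||model||_F``; both stay PSD and the
    relative difference matches the requested scale.
    """
    model = synth_psd_matrix(spec)
    if spec.perturbation == 0.0:
        return model, model.copy()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    r_pert = min(2 * spec.rank, spec.d)
    g = rng.standard_normal((spec.d, r_pert))
    e = g @ g.T
    e *= spec.perturbation * np.linalg.norm(model) / np.linalg.norm(e)
    return model, model + e


def synth_two_rdm(n_orb: int, n_alpha: int, n_beta: int, rank: int,
                  decay: float = 1.0, coherence: float = 0.0,
                  perturbation: float = 0.0, seed: int = 0
                  ) -> tuple[TwoRDM, TwoRDM]:
    """A synthetic (model, target) pair of 2-RDM containers.

    Each populated sector is an independent synthetic PSD matrix with the
    requested head rank and tail decay, trace-normalized to its
    electron-count target so postprocessing is well defined.  The matrices
    carry the spectral statistics of correlated 2-RDMs but are not
    N-representable; they exercise the noiseless pipeline only.
    """
    from .rdm_model import sector_trace_targets

    targets = sector_trace_targets(n_alpha, n_beta)
    labels = ["abab"]
    if n_alpha >= 2:
        labels.append("aaaa")
    if n_beta >= 2:
        labels.append("bbbb")
    model_sectors, target_sectors = {}, {}
    for off, label in enumerate(labels):
        d = sector_dim(label, n_orb)
        spec = SyntheticSpec(d=d, rank=min(rank, d), decay=decay,
                             coherence=coherence,
                             perturbation=perturbation,
                             seed=seed + 17 * off)
        m, t = synth_model_target_pair(spec)
        tt = targets[label] if targets[label] > 0 else 1.0
        model_sectors[label] = PackedSectorMatrix(
            label, n_orb, m * (tt / np.trace(m)))
        target_sectors[label] = PackedSectorMatrix(
            label, n_orb, t * (tt / np.trace(t)))
    return (TwoRDM(model_sectors, n_orb, n_alpha, n_beta),
            TwoRDM(target_sectors, n_orb, n_alpha, n_beta))


# ---------------------------------------------------------------------------
# toy-molecule fixtures: a minimal electronic-structure engine
# ---------------------------------------------------------------------------

class ElectronicStructureBackend(Protocol):
    """Adapter contract for plugging in a real electronic-structure code.

    An implementation computes a cheap model 2-RDM (e.g. unrelaxed MP2),
    an accurate target 2-RDM (e.g. CCSD) and the matching active-space
    integrals for a molecule/basis, with ``frozen_core`` low orbitals
    folded into ``e_core``.  The test suite never requires one.
    """

    def compute_rdms(self, molecule: str, basis: str, frozen_core: int
                     ) -> tuple[TwoRDM, TwoRDM, MolecularIntegrals]:
        ...


def _toy_integrals(n: int, seed: int, t_spread: float = 2.7,
                   t_off: float = 0.05, v_coulomb: float = 0.4,
                   v_random: float = 0.15) -> MolecularIntegrals:
    """Seeded toy integrals with full 8-fold symmetry and a PSD 2e kernel.

    The one-electron part is a diagonally dominant matrix with ascending
    levels; the two-electron part is a Coulomb-like diagonal kernel plus a
    random PSD supermatrix projected onto the 8-fold-symmetric subspace.
    All values in Hartree-scale units.
    """
    rng = np.random.default_rng(seed)
    levels = -3.0 + t_spread * np.arange(n) / max(n - 1, 1)
    t = np.diag(levels)
    off = t_off * rng.standard_normal((n, n))
    t = t + np.triu(off, 1) + np.triu(off, 1).T

    # chemists' (ij|kl) kernel
    chem = np.zeros((n, n, n, n))
    for i in range(n):
        for k in range(n):
            chem[i, i, k, k] = v_coulomb / (1.0 + abs(i - k))
    b = rng.standard_normal((n * n, n * n))
    s = (b @ b.T) / (n * n)
    sten = s.reshape(n, n, n, n)
    # project onto i<->j and k<->l symmetry (keeps the supermatrix PSD),
    # then symmetrize the (ij)<->(kl) exchange
    sten = 0.25 * (sten + sten.transpose(1, 0, 2, 3)
                   + sten.transpose(0, 1, 3, 2)
                   + sten.transpose(1, 0, 3, 2))
    sten = 0.5 * (sten + sten.transpose(2, 3, 0, 1))
    chem += v_random * sten
    # physicists' <ik|jl> = (ij|kl)
    v_phys = chem.transpose(0, 2, 1, 3)
    return MolecularIntegrals(t, v_phys, e_core=0.0)


def _uhf(ints: MolecularIntegrals, n_alpha: int, n_beta: int,
         max_cycle: int = 200, tol: float = 1e-11
         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Unrestricted Hartree-Fock in the toy basis.

    Returns the alpha and beta molecular-orbital coefficient matrices
    (columns ordered by orbital energy) and the converged UHF energy.
    """
    n = ints.n_orb
    chem = ints.v.transpose(0, 2, 1, 3)  # back to (ij|kl)
    t = ints.t

    def fock(da: np.ndarray, db: np.ndarray):
        j = np.einsum("ijkl,kl->ij", chem, da + db)
        ka = np.einsum("ikjl,kl->ij", chem, da)
        kb = np.einsum("ikjl,kl->ij", chem, db)
        return t + j - ka, t + j - kb

    def density(c: np.ndarray, nocc: int) -> np.ndarray:
        occ = c[:, :nocc]
        return occ @ occ.T

    ca = cb = np.eye(n)
    da, db = density(ca, n_alpha), density(cb, n_beta)
    e_old = np.inf
    for _ in range(max_cycle):
        fa, fb = fock(da, db)
        _, ca = np.linalg.eigh(fa)
        _, cb = np.linalg.eigh(fb)
        da_new, db_new = density(ca, n_alpha), density(cb, n_beta)
        da = 0.7 * da_new + 0.3 * da  # damped update
        db = 0.7 * db_new + 0.3 * db
        e = (0.5 * np.einsum("ij,ij->", t + fa, da)
             + 0.5 * np.einsum("ij,ij->", t + fb, db))
        if abs(e - e_old) < tol:
            da, db = da_new, db_new
            break
        e_old = e
    fa, fb = fock(da, db)
    _, ca = np.linalg.eigh(fa)
    _, cb = np.linalg.eigh(fb)
    e = (0.5 * np.einsum("ij,ij->", t + fa, da)
         + 0.5 * np.einsum("ij,ij->", t + fb, db)) + ints.e_core
    return ca, cb, float(e)


def _mo_integrals(ints: MolecularIntegrals, c: np.ndarray
                  ) -> MolecularIntegrals:
    t = c.T @ ints.t @ c
    v = np.einsum("pi,qk,rj,sl,pqrs->ikjl", c, c, c, c, ints.v,
                  optimize=True)
    return MolecularIntegrals(t, v, ints.e_core)


def _freeze_core(ints: MolecularIntegrals, n_core: int) -> MolecularIntegrals:
    """Fold doubly occupied core orbitals into the active-space integrals."""
    if n_core == 0:
        return ints
    chem = ints.v.transpose(0, 2, 1, 3)
    core = range(n_core)
    act = slice(n_core, ints.n_orb)
    e_core = ints.e_core + 2.0 * sum(ints.t[c, c] for c in core)
    for c in core:
        for cc in core:
            e_core += 2.0 * chem[c, c, cc, cc] - chem[c, cc, cc, c]
    t_act = ints.t[act, act].copy()
    for c in core:
        t_act += (2.0 * chem[act, act, c, c] - chem[act, c, c, act])
    v_act = ints.v[act, act, act, act].copy()
    return MolecularIntegrals(t_act, v_act, float(e_core))


# -- second-quantized machinery on the active space (blocked JW order) ------

@lru_cache(maxsize=8)
def _annihilators(n_so: int) -> tuple:
    """Sparse JW annihilation operators; site 0 is the leftmost factor."""
    z = sp.csr_matrix(np.diag([1.0, -1.0]))
    sm = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))  # a: |1> -> |0>
    eye = sp.identity(2, format="csr")
    ops = []
    for site in range(n_so):
        m = sp.identity(1, format="csr")
        for k in range(n_so):
            f = z if k < site else (sm if k == site else eye)
            m = sp.kron(m, f, format="csr")
        ops.append(m)
    return tuple(ops)


def _build_hamiltonian(ints: MolecularIntegrals, n_so: int) -> sp.csr_matrix:
    n = ints.n_orb
    ann = _annihilators(n_so)
    epq = {}
    for p in range(n_so):
        for q in range(n_so):
            if (p < n) == (q < n):  # spin conserving
                epq[(p, q)] = (ann[p].conj().T @ ann[q]).tocsr()
    h = sp.csr_matrix((2 ** n_so, 2 ** n_so))
    for p in range(n_so):
        for q in range(n_so):
            if (p < n) == (q < n):
                h = h + ints.t[p % n, q % n] * epq[(p, q)]
    # 1/2 sum V_pqrs a†_p a†_q a_s a_r  =  1/2 sum V (E_pr E_qs - d_qr E_ps)
    for p in range(n_so):
        for r in range(n_so):
            if (p < n) != (r < n):
                continue
            w = sp.csr_matrix((2 ** n_so, 2 ** n_so))
            for q in range(n_so):
                for s_ in range(n_so):
                    if (q < n) != (s_ < n):
                        continue
                    w = w + ints.v[p % n, q % n, r % n, s_ % n] * epq[(q, s_)]
            h = h + 0.5 * (epq[(p, r)] @ w)
            # delta term: q == r
            for s_ in range(n_so):
                if (r < n) == (s_ < n):
                    h = h - 0.5 * ints.v[p % n, r % n, r % n, s_ % n] \
                        * epq[(p, s_)]
    return h.tocsr()


def _sector_indices(n_so: int, n_alpha: int, n_beta: int) -> np.ndarray:
    n = n_so // 2
    idx = []
    for b in range(2 ** n_so):
        bits = [(b >> (n_so - 1 - s)) & 1 for s in range(n_so)]
        if sum(bits[:n]) == n_alpha and sum(bits[n:]) == n_beta:
            idx.append(b)
    return np.array(idx, dtype=int)


def _aufbau_index(n_so: int, n_alpha: int, n_beta: int) -> int:
    n = n_so // 2
    b = 0
    for s in list(range(n_alpha)) + [n + x for x in range(n_beta)]:
        b |= 1 << (n_so - 1 - s)
    return b


def _rdms_from_state(psi: np.ndarray, n: int, n_alpha: int, n_beta: int
                     ) -> tuple[TwoRDM, OneRDM]:
    """1- and 2-RDMs of a statevector via pair-annihilated inner products."""
    n_so = 2 * n
    ann = _annihilators(n_so)
    single = [ann[p] @ psi for p in range(n_so)]
    pair = {}
    for x in range(n_so):
        for y in range(n_so):
            if x != y:
                pair[(x, y)] = ann[x] @ single[y]  # a_x a_y psi

    def two_body(i: int, k: int, l: int, j: int) -> float:
        #  <a†_i a†_k a_l a_j> = <a_k a_i psi | a_l a_j psi>
        if i == k or l == j:
            return 0.0
        return float(pair[(k, i)] @ pair[(l, j)])

    sectors = {}
    t_ab = np.zeros((n, n, n, n))
    for i in range(n):
        for k in range(n):
            for j in range(n):
                for l in range(n):
                    t_ab[i, k, j, l] = two_body(i, k + n, l + n, j)
    sectors["abab"] = pack_sector(t_ab, "abab")
    for label, off, count in (("aaaa", 0, n_alpha), ("bbbb", n, n_beta)):
        if count < 2:
            continue
        tt = np.zeros((n, n, n, n))
        for i in range(n):
            for k in range(n):
                for j in range(n):
                    for l in range(n):
                        tt[i, k, j, l] = two_body(i + off, k + off,
                                                  l + off, j + off)
        sectors[label] = pack_sector(tt, label)
    da = np.array([[float(single[i] @ single[j])
                    for j in range(n)] for i in range(n)])
    db = np.array([[float(single[i + n] @ single[j + n])
                    for j in range(n)] for i in range(n)])
    rdm2 = TwoRDM(sectors, n, n_alpha, n_beta)
    return rdm2, OneRDM(da, db)


# -- presets ----------------------------------------------------------------

@dataclass
class ToyFixture:
    """A solved toy system: model/target 2-RDMs plus matching integrals.

    ``model`` is the first-order perturbative 2-RDM, ``target`` the exact
    (full-diagonalization) 2-RDM, both over the active space in the
    canonical UHF orbital basis.  ``e_target`` is the exact total energy
    and ``e_hf`` the mean-field energy, for closed-form checks.
    """

    name: str
    model: TwoRDM
    target: TwoRDM
    ints: MolecularIntegrals
    model_1rdm: OneRDM
    target_1rdm: OneRDM
    e_hf: float
    e_target: float

    def __iter__(self):
        return iter((self.model, self.target, self.ints))


# name -> (n_orb, n_alpha, n_beta, frozen_core, integral seed, overrides)
_PRESETS: dict[str, tuple] = {
    # single spatial orbital, two electrons: energy in closed form,
    # t11 = -1.25, (11|11) = 0.675  =>  E = 2 t + v = -1.825
    "one_orbital": (1, 1, 1, 0, 0, {"explicit": True}),
    # two-electron pairs in growing spaces: abab sector only, low rank
    "pair_n3": (3, 1, 1, 0, 11, {}),
    "pair_n4": (4, 1, 1, 0, 12, {}),
    "pair_n5": (5, 1, 1, 0, 13, {}),
    # LiH-like: 4 electrons, frozen core -> 2 active electrons, abab only
    "lih_like": (5, 2, 2, 1, 21, {}),
    # BeH-like: 5 electrons, frozen core -> open shell (2, 1) in 5 orbitals
    "beh_like": (6, 3, 2, 1, 22, {}),
    # closed shell, all three sectors populated
    "closed_shell": (5, 2, 2, 0, 31, {}),
}


def toy_presets() -> list[str]:
    return list(_PRESETS)


@lru_cache(maxsize=None)
def toy_molecule_fixtures(preset: str) -> ToyFixture:
    """Build and solve a toy-molecule preset.

    Pipeline: toy integrals -> UHF -> canonical-MO transform (alpha
    orbitals; the beta MO basis is taken equal for a spin-free active
    Hamiltonian) -> frozen-core folding -> exact diagonalization (target)
    and Epstein-Nesbet first-order perturbation (model).
    """
    if preset not in _PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}")
    n_tot, n_alpha_tot, n_beta_tot, n_core, seed, opts = _PRESETS[preset]

    if opts.get("explicit"):
        t = np.array([[-1.25]])
        v = np.full((1, 1, 1, 1), 0.675)
        ints = MolecularIntegrals(t, v, 0.0)
        ca = np.eye(1)
    else:
        ints = _toy_integrals(n_tot, seed)
        ca, _cb, _e = _uhf(ints, n_alpha_tot, n_beta_tot)
    # a single spatial MO basis keeps the active integrals spin-free
    ints_mo = _mo_integrals(ints, ca)
    ints_act = _freeze_core(ints_mo, n_core)

    n = ints_act.n_orb
    n_alpha = n_alpha_tot - n_core
    n_beta = n_beta_tot - n_core
    n_so = 2 * n
    h = _build_hamiltonian(ints_act, n_so)
    idx = _sector_indices(n_so, n_alpha, n_beta)
    h_sec = h[np.ix_(idx, idx)].toarray()
    evals, evecs = np.linalg.eigh(h_sec)
    psi_t = np.zeros(2 ** n_so)
    psi_t[idx] = evecs[:, 0]
    e_target = float(evals[0] + ints_act.e_core)

    hf_pos = int(np.where(idx == _aufbau_index(n_so, n_alpha, n_beta))[0][0])
    e_hf = float(h_sec[hf_pos, hf_pos] + ints_act.e_core)
    if evecs[hf_pos, 0] ** 2 < 0.6:
        raise RuntimeError(
            f"preset {preset!r}: ground state is not dominated by the "
            "aufbau determinant; the perturbative model is invalid here")
    # Epstein-Nesbet first order: c_D = H_D,HF / (H_HF,HF - H_D,D)
    diag = np.diag(h_sec)
    denom = diag[hf_pos] - diag
    coupling = h_sec[:, hf_pos].copy()
    c = np.zeros_like(coupling)
    mask = np.abs(denom) > 1e-9
    c[mask] = coupling[mask] / denom[mask]
    c[hf_pos] = 1.0
    c /= np.linalg.norm(c)
    psi_m = np.zeros(2 ** n_so)
    psi_m[idx] = c

    target, target_1 = _rdms_from_state(psi_t, n, n_alpha, n_beta)
    model, model_1 = _rdms_from_state(psi_m, n, n_alpha, n_beta)
    target.frozen_core = n_core
    model.frozen_core = n_core
    return ToyFixture(preset, model, target, ints_act, model_1, target_1,
                      e_hf, e_target)
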