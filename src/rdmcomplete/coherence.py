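"""Geometric coherence of 2-RDM sectors and its minimization by orbital rotation.

Uniform element sampling completes a low-rank matrix efficiently only when
the information is spread evenly over its entries.  This is quantified by
the geometric coherence of the top-``r`` singular subspace ``U``:

    mu = (d / r) * max_i ||row_i(U)||^2,        1 <= mu <= d/r.

The canonical molecular-orbital basis tends to be nearly maximally coherent,
so before sampling we rotate the orbitals by an orthogonal matrix ``C``
chosen to minimize the coherence of the *model* 2-RDM.  The non-smooth max
is replaced by a power-mean surrogate  sum_i ||row_i(U)||^(2p)  (p = 8 by
default), minimized over skew-symmetric generators ``C = C0 exp(A)`` from
several Haar-random starts; the start with the lowest surrogate wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .rdm_model import (
    MolecularIntegrals,
    PackedSectorMatrix,
    TwoRDM,
    pack_sector,
    unpack_sector,
)

__all__ = [
    "OrbitalRotation",
    "geometric_coherence",
    "haar_orthogonal",
    "rotate_2rdm",
    "rotate_integrals",
    "minimize_coherence",
]

_ORTHO_TOL = 1e-10


@dataclass
class OrbitalRotation:
    """Orthogonal spatial-orbital rotations, one per spin channel.

    Columns of ``c_alpha``/``c_beta`` are the new orbitals expanded in the
    old basis.  A spin-restricted rotation has ``c_alpha is c_beta``.
    """

    c_alpha: np.ndarray
    c_beta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("c_alpha", "c_beta"):
            c = np.asarray(getattr(self, name), dtype=float)
            n = c.shape[0]
            if c.shape != (n, n):
                raise ValueError(f"{name} must be square")
            if np.abs(c.T @ c - np.eye(n)).max() > _ORTHO_TOL:
                raise ValueError(f"{name} is not orthogonal")
            setattr(self, name, c)

    @property
    def n_orb(self) -> int:
        return self.c_alpha.shape[0]

    @property
    def is_restricted(self) -> bool:
        return np.array_equal(self.c_alpha, self.c_beta)

    @classmethod
    def identity(cls, n: int) -> "OrbitalRotation":
        return cls(np.eye(n), np.eye(n))


def geometric_coherence(m: PackedSectorMatrix | np.ndarray, r: int) -> float:
    """Geometric coherence ``(d/r) max_i ||row_i(U)||^2`` of the top-r subspace.

    ``U`` holds the ``r`` leading singular vectors.  When ``r`` exceeds the
    numerical rank the value is still computed on the top-``r`` subspace,
    whose trailing directions are then arbitrary within the null space.
    """
    a = m.values if isinstance(m, PackedSectorMatrix) else np.asarray(m)
    d = a.shape[0]
    if not 1 <= r <= d:
        raise ValueError(f"rank {r} outside [1, {d}]")
    u, _, _ = np.linalg.svd(a)
    lev = np.sum(u[:, :r] ** 2, axis=1)
    return float(d / r * lev.max())


def haar_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-distributed orthogonal matrix via sign-fixed QR."""
    q, rr = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(rr))


def rotate_2rdm(rdm2: TwoRDM, rot: OrbitalRotation) -> TwoRDM:
    """Transform every sector into the rotated orbital basis.

    Same-spin sectors receive their channel's rotation on all four indices;
    the abab sector receives ``c_alpha`` on the alpha pair (i, j) and
    ``c_beta`` on the beta pair (k, l).  Packed traces — and the energy,
    when the integrals are co-rotated — are invariant.
    """
    if rot.n_orb != rdm2.n_orb:
        raise ValueError("rotation dimension does not match active space")
    cs = {"a": rot.c_alpha, "b": rot.c_beta}
    sectors = {}
    for label, sec in rdm2.sectors.items():
        t = unpack_sector(sec)
        ci, ck = cs[label[0]], cs[label[1]]
        # new_{ikjl} = sum_{pqrs} C_pi C_qk C_rj C_sl old_{pqrs}
        t = np.einsum("pi,qk,rj,sl,pqrs->ikjl", ci, ck, ci, ck, t,
                      optimize=True)
        sectors[label] = pack_sector(t, label)
    return TwoRDM(sectors, rdm2.n_orb, rdm2.n_alpha, rdm2.n_beta,
                  rdm2.frozen_core)


def rotate_integrals(ints: MolecularIntegrals,
                     rot: OrbitalRotation) -> MolecularIntegrals:
    """Co-rotate spin-free integrals (requires a spin-restricted rotation)."""
    if not rot.is_restricted:
        raise ValueError(
            "spin-free integrals can only be co-rotated by a restricted "
            "(shared alpha/beta) orbital rotation")
    c = rot.c_alpha
    t = c.T @ ints.t @ c
    v = np.einsum("pi,qk,rj,sl,pqrs->ikjl", c, c, c, c, ints.v,
                  optimize=True)
    return MolecularIntegrals(t, v, ints.e_core)


# ---------------------------------------------------------------------------
# coherence minimization
# ---------------------------------------------------------------------------

def _leverage_objective(m: np.ndarray, r: int, p: int) -> float:
    """Power-mean surrogate of the coherence: sum_i ||row_i(U)||^(2p)."""
    u, _, _ = np.linalg.svd(m)
    lev = np.sum(u[:, :r] ** 2, axis=1)
    return float(np.sum(lev ** p))


def _skew(params: np.ndarray, n: int) -> np.ndarray:
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    a[iu] = params
    return a - a.T


def _rotation_from_params(params: np.ndarray, base: list[np.ndarray],
                          restricted: bool, n: int) -> OrbitalRotation:
    npar = n * (n - 1) // 2
    if restricted:
        c = base[0] @ expm(_skew(params, n))
        return OrbitalRotation(c, c)
    ca = base[0] @ expm(_skew(params[:npar], n))
    cb = base[1] @ expm(_skew(params[npar:], n))
    return OrbitalRotation(ca, cb)


def minimize_coherence(
    model: TwoRDM,
    ranks: dict[str, int],
    n_starts: int = 10,
    seed: int | None = None,
    p: int = 8,
    spin_restricted: bool = True,
    max_iter: int = 150,
) -> tuple[OrbitalRotation, dict]:
    """Find an orbital rotation that minimizes the model 2-RDM's coherence.

    The smoothed objective sums the per-sector leverage surrogates at each
    sector's selected rank, with equal weights (one measurement basis must
    serve all sectors).  ``n_starts`` Haar-random initial rotations are
    tried in addition to the identity; a start whose local optimization
    fails is discarded, and the retained start with the lowest surrogate is
    returned.

    Returns the rotation and a report with per-sector coherence before and
    after, the surrogate objectives, and the per-start outcomes.
    """
    labels = [s for s in model.sectors if ranks.get(s, 0) >= 1]
    if not labels:
        raise ValueError("no sector has a rank >= 1 to optimize")
    n = model.n_orb
    rng = np.random.default_rng(seed)
    npar = n * (n - 1) // 2
    dim = npar if spin_restricted else 2 * npar

    def objective(params: np.ndarray, base: list[np.ndarray]) -> float:
        rot = _rotation_from_params(params, base, spin_restricted, n)
        rotated = rotate_2rdm(model, rot)
        return sum(
            _leverage_objective(rotated.sectors[s].values, ranks[s], p)
            for s in labels
        )

    starts: list[list[np.ndarray]] = [[np.eye(n), np.eye(n)]]
    for _ in range(n_starts):
        ca = haar_orthogonal(n, rng)
        cb = ca if spin_restricted else haar_orthogonal(n, rng)
        starts.append([ca, cb])

    best: tuple[float, OrbitalRotation] | None = None
    start_objectives: list[float] = []
    n_failed = 0
    for base in starts:
        try:
            res = minimize(
                objective, np.zeros(dim), args=(base,),
                method="L-BFGS-B",
                options={"maxiter": max_iter, "eps": 1e-7},
            )
            obj = float(res.fun)
            rot = _rotation_from_params(res.x, base, spin_restricted, n)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        start_objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, rot)
    if best is None:
        raise RuntimeError("coherence minimization failed on every start")

    obj_best, rot = best
    rotated = rotate_2rdm(model, rot)
    mu_before = {s: geometric_coherence(model.sectors[s], ranks[s])
                 for s in labels}
    mu_after = {s: geometric_coherence(rotated.sectors[s], ranks[s])
                for s in labels}
    report = {
        "mu_before": mu_before,
        "mu_after": mu_after,
        "objective": obj_best,
        "start_objectives": start_objectives,
        "n_failed_starts": n_failed,
    }
    return rot, report
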