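"""Factorized low-rank completion of symmetric positive semidefinite matrices.

A rank-``r`` approximation of a symmetric PSD ``d x d`` matrix ``M`` is
recovered from a subset Omega of its unique (lower-triangular) elements by
minimizing

    sum_{(i,j) in Omega} [ (L^T L)_ij - M_ij ]^2

over a real ``r x d`` factor ``L`` with a quasi-Newton method (L-BFGS-B).
The ``L^T L`` parametrization keeps every iterate symmetric PSD by
construction.  The module also provides uniform element sampling, the
relative Frobenius error metric, and the information bound
``(2rd - r^2 + r)/(d(d+1))`` — the fraction of unique elements below which a
rank-``r`` symmetric matrix is underdetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SampleSet",
    "CompletionResult",
    "sample_elements",
    "complete",
    "relative_error",
    "information_bound",
]


@dataclass(frozen=True)
class SampleSet:
    """A set of unique sampled elements of a symmetric ``d x d`` matrix.

    Indices are (row, col) with ``row >= col``; sampling is uniform without
    replacement over the ``d(d+1)/2`` unique elements and reproducible from
    ``seed``.
    """

    d: int
    indices: tuple[tuple[int, int], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for (i, j) in self.indices:
            if not (0 <= j <= i < self.d):
                raise ValueError(f"index ({i},{j}) outside lower triangle "
                                 f"of a {self.d}x{self.d} matrix")
            if (i, j) in seen:
                raise ValueError(f"duplicate sampled element ({i},{j})")
            seen.add((i, j))

    @property
    def n_sample(self) -> int:
        return len(self.indices)

    @property
    def f_sample(self) -> float:
        return self.n_sample / (self.d * (self.d + 1) / 2)

    def values_from(self, m: np.ndarray) -> dict[tuple[int, int], float]:
        return {(i, j): float(m[i, j]) for (i, j) in self.indices}


@dataclass
class CompletionResult:
    factor: np.ndarray                  # r x d
    completed: np.ndarray               # d x d, L^T L
    objective: float
    trajectory: np.ndarray              # objective at accepted iterates
    iterations: int
    converged: bool
    relative_error: float | None = None
    restart_objectives: list[float] = field(default_factory=list)


def sample_elements(d: int, n_sample: int | None = None,
                    f_sample: float | None = None,
                    rng_seed: int | None = None) -> SampleSet:
    """Uniform sample of unique elements of a symmetric ``d x d`` matrix.

    Exactly one of ``n_sample`` / ``f_sample`` must be given; ``f_sample`` is
    converted with ceiling so any positive fraction samples at least one
    element.
    """
    n_unique = d * (d + 1) // 2
    if (n_sample is None) == (f_sample is None):
        raise ValueError("give exactly one of n_sample or f_sample")
    if n_sample is None:
        if not 0.0 < f_sample <= 1.0:
            raise ValueError("f_sample must lie in (0, 1]")
        n_sample = int(np.ceil(f_sample * n_unique))
    if not 0 < n_sample <= n_unique:
        raise ValueError(
            f"n_sample={n_sample} outside (0, {n_unique}] for d={d}")
    rng = np.random.default_rng(rng_seed)
    flat = rng.choice(n_unique, size=n_sample, replace=False)
    rows, cols = np.tril_indices(d)
    idx = tuple((int(rows[a]), int(cols[a])) for a in sorted(flat.tolist()))
    return SampleSet(d, idx, rng_seed)


def relative_error(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Relative error in the Frobenius norm, ``|est - ref|_F / |ref|_F``."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    denom = np.linalg.norm(ref)
    if denom == 0.0:
        raise ValueError("reference matrix is zero")
    return float(np.linalg.norm(est - ref) / denom)


def information_bound(r: int, d: int) -> float:
    """Fraction of unique elements needed to determine a rank-r symmetric matrix.

    The ratio of the degrees of freedom of a rank-``r`` symmetric ``d x d``
    matrix, ``rd - r(r-1)/2``, to the ``d(d+1)/2`` unique elements:
    ``(2rd - r^2 + r) / (d(d+1))``.
    """
    if not 0 <= r <= d:
        raise ValueError(f"rank {r} outside [0, {d}]")
    return (2 * r * d - r * r + r) / (d * (d + 1))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class _ExplodedRun(Exception):
    """Raised from the optimizer callback to abandon a diverging start."""


class _FailedResult:
    """Stand-in optimizer result when every start diverged."""

    def __init__(self, l0: np.ndarray):
        self.x = l0.ravel()
        self.fun = float("inf")
        self.nit = 0
        self.success = False

def _objective_grad(l_flat: np.ndarray, r: int, d: int,
                    rows: np.ndarray, cols: np.ndarray,
                    vals: np.ndarray) -> tuple[float, np.ndarray]:
    """Misfit on Omega and its gradient w.r.t. the flattened factor.

    Each unique element enters once; the symmetric-gradient weight is 2 for
    off-diagonal representatives and 4 on the diagonal (the diagonal entry of
    L^T L depends quadratically on the same column of L).
    """
    L = l_flat.reshape(r, d)
    est = np.sum(L[:, rows] * L[:, cols], axis=0)
    e = est - vals
    obj = float(np.dot(e, e))
    # assemble the symmetric weight matrix A with A_ij = A_ji = 2 e_ij
    # (off-diagonal) and A_ii = 4 e_ii, nonzero only on Omega
    a = np.zeros((d, d))
    np.add.at(a, (rows, cols), 2.0 * e)
    np.add.at(a, (cols, rows), 2.0 * e)  # doubles the diagonal, as required
    grad = L @ a
    return obj, grad.ravel()


def _initial_factor(observed: dict[tuple[int, int], float], d: int, r: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Warm start: truncated eigenfactor of the zero-filled observed matrix
    plus small seeded Gaussian noise."""
    m0 = np.zeros((d, d))
    for (i, j), v in observed.items():
        m0[i, j] = v
        m0[j, i] = v
    w, u = np.linalg.eigh(m0)
    order = np.argsort(w)[::-1][:r]
    lam = np.clip(w[order], 0.0, None)
    L = (u[:, order] * np.sqrt(lam)).T
    if L.shape[0] < r:
        L = np.vstack([L, np.zeros((r - L.shape[0], d))])
    scale = 1e-2 * max(np.linalg.norm(m0), 1e-8)
    return L + scale / max(d, 1) * rng.standard_normal((r, d))


def complete(observed: dict[tuple[int, int], float], d: int, r: int,
             max_iter: int = 15000, grad_tol: float = 1e-10,
             n_restarts: int = 1, seed: int | None = None,
             reference: np.ndarray | None = None,
             max_retries: int = 3) -> CompletionResult:
    """Complete a symmetric PSD matrix from observed unique elements.

    Minimizes the squared misfit on Omega over a rank-``r`` factor with
    L-BFGS-B, returning the best of ``n_restarts`` seeded warm starts (ties
    broken by start order).  The factorized objective has spurious local
    minima where the factor norm explodes while fitting Omega; a solution
    whose completed norm far exceeds the full-matrix norm extrapolated from
    the observed entries is rejected, triggering up to ``max_retries``
    fresh starts.  If every start is rejected, or the optimizer reports
    failure, the best result is still returned with ``converged=False`` so
    callers can exclude it from averages.
    """
    if r < 1:
        raise ValueError("rank must be at least 1")
    if not observed:
        raise ValueError("no observed elements")
    rows = np.array([i for (i, j) in observed], dtype=int)
    cols = np.array([j for (i, j) in observed], dtype=int)
    if rows.size and (rows.max() >= d or cols.max() >= d):
        raise ValueError("observed index outside matrix")
    vals = np.array([observed[(i, j)] for (i, j) in observed], dtype=float)
    # norm of the full matrix extrapolated from a uniform sample
    n_unique = d * (d + 1) / 2
    norm_est = np.sqrt(float(np.sum(vals ** 2)) * n_unique / vals.size)

    rng = np.random.default_rng(seed)
    # the factor's squared norm equals trace(L^T L), at most ~sqrt(d) times
    # the Frobenius norm for a legitimate PSD completion
    explosion_bound = max(10.0, 3.0 * np.sqrt(d)) * max(norm_est, 1e-30)
    best = None          # (exploded, objective, res, traj)
    restart_objectives: list[float] = []
    attempts_left = n_restarts + max_retries
    n_starts_done = 0
    while attempts_left > 0:
        attempts_left -= 1
        n_starts_done += 1
        l0 = _initial_factor(observed, d, r, rng)
        traj: list[float] = []

        def callback(xk):
            traj.append(_objective_grad(xk, r, d, rows, cols, vals)[0])
            # abandon runs drifting into the spurious large-norm region
            if float(xk @ xk) > explosion_bound:
                raise _ExplodedRun

        try:
            res = minimize(
                _objective_grad, l0.ravel(), args=(r, d, rows, cols, vals),
                jac=True, method="L-BFGS-B", callback=callback,
                options={"maxiter": max_iter, "gtol": grad_tol,
                         "ftol": 1e-18},
            )
        except _ExplodedRun:
            restart_objectives.append(float("inf"))
            if best is None:
                best = (True, float("inf"), _FailedResult(l0), np.array(traj))
            continue
        obj = float(res.fun)
        restart_objectives.append(obj)
        exploded = float(res.x @ res.x) > explosion_bound
        key = (exploded, obj)
        if best is None or key < (best[0], best[1]):
            best = (exploded, obj, res, np.array(traj))
        # stop early once the requested eager restarts are done and a
        # sane solution exists
        if n_starts_done >= n_restarts and not best[0]:
            break
    exploded, obj, res, traj = best
    converged = (bool(res.success) or obj < 1e-20) and not exploded
    if not exploded and np.isfinite(obj) and obj > 0.0:
        # a fresh quasi-Newton memory often advances past the stall point
        # of the first pass near the objective's numerical floor; an
        # abnormal line-search ending here cannot undo convergence
        polish = minimize(
            _objective_grad, res.x, args=(r, d, rows, cols, vals),
            jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": min(grad_tol, 1e-12),
                     "ftol": 1e-20},
        )
        if float(polish.fun) < obj:
            obj = float(polish.fun)
            res = polish
            converged = converged or bool(polish.success)
    L = res.x.reshape(r, d)
    completed = L.T @ L
    rel = None
    if reference is not None:
        rel = relative_error(completed, reference)
    return CompletionResult(
        factor=L, completed=completed, objective=obj,
        trajectory=traj, iterations=int(res.nit), converged=converged,
        relative_error=rel, restart_objectives=restart_objectives,
    )
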