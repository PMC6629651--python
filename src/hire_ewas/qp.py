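"""Small simplex-constrained quadratic programs.

Solves  min_p  p' A p - 2 b' p   subject to  sum(p) = 1, p >= 0,

with A symmetric positive (semi)definite and K small (the number of cell
types).  A primal active-set method on the nonnegativity constraints is used:
each step solves the equality-constrained KKT system on the free coordinates;
a negative free coordinate joins the active set, and on a feasible iterate
the most negative Lagrange multiplier leaves it.  For strictly convex
problems this terminates at the exact optimum; a projected-gradient fallback
guards the (rare) degenerate case.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_simplex_qp", "SimplexQPError"]


class SimplexQPError(RuntimeError):
    pass


def _solve_free(A: np.ndarray, b: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Equality-constrained minimiser on the free coordinates.

    Stationarity: 2 A_FF p_F - 2 b_F + lam 1 = 0, 1' p_F = 1.
    """
    nf = free.size
    KKT = np.zeros((nf + 1, nf + 1))
    KKT[:nf, :nf] = 2.0 * A[np.ix_(free, free)]
    KKT[:nf, nf] = 1.0
    KKT[nf, :nf] = 1.0
    rhs = np.concatenate([2.0 * b[free], [1.0]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
    return sol[:nf], float(sol[nf])


def _projected_gradient(A: np.ndarray, b: np.ndarray, max_iter: int = 5000) -> np.ndarray:
    K = A.shape[0]
    p = np.full(K, 1.0 / K)
    # Lipschitz constant of the gradient 2(Ap - b)
    L = 2.0 * max(float(np.linalg.eigvalsh(A)[-1]), 1e-12)
    step = 1.0 / L
    for _ in range(max_iter):
        g = 2.0 * (A @ p - b)
        p_new = _project_simplex(p - step * g)
        if np.max(np.abs(p_new - p)) < 1e-14:
            return p_new
        p = p_new
    return p


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    cond = u - css / idx > 0
    rho = idx[cond][-1]
    theta = css[rho - 1] / rho
    return np.maximum(v - theta, 0.0)


def solve_simplex_qp(
    A: np.ndarray, b: np.ndarray, max_iter: int = 200, tol: float = 1e-12
) -> np.ndarray:
    """Exact minimiser of p'Ap - 2b'p on the probability simplex."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    K = b.size
    if K == 1:
        return np.array([1.0])

    active = np.zeros(K, dtype=bool)  # coordinates pinned at zero
    for _ in range(max_iter):
        free = np.flatnonzero(~active)
        if free.size == 0:  # numerically degenerate; fall back
            break
        p_free, lam = _solve_free(A, b, free)
        if np.min(p_free) < -tol:
            # pin the most negative free coordinate and re-solve
            active[free[int(np.argmin(p_free))]] = True
            continue
        p = np.zeros(K)
        p[free] = np.clip(p_free, 0.0, None)
        p /= p.sum()
        # KKT multipliers of the pinned coordinates: grad_i + lam >= 0
        if not active.any():
            return p
        grad = 2.0 * (A @ p - b)
        mult = grad[active] + lam
        if np.min(mult) >= -1e-9 * max(1.0, np.max(np.abs(grad))):
            return p
        pinned = np.flatnonzero(active)
        active[pinned[int(np.argmin(mult))]] = False
    # fallback: projected gradient (always feasible, near-optimal)
    return _projected_gradient(A, b)
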