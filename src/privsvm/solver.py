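"""Simplex-constrained quadratic programming.

The dual of the l2-SVMp+ model has the one-class-SVM shape

    minimize  (1/2) a' G a   subject to  a >= 0,  sum(a) = 1,

with G symmetric positive semidefinite.  :func:`smo_solve` minimizes it with a
sequential-minimal-optimization pair update (maximal-violating-pair working-set
selection); :func:`qp_oracle` solves the identical problem with a generic
smooth constrained optimizer and exists for cross-checking and tiny problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["QPResult", "smo_solve", "qp_oracle", "kkt_residuals"]

logger = logging.getLogger(__name__)

#: refresh the maintained gradient from scratch this often, to bound fp drift
_REFRESH_EVERY = 4096


@dataclass
class QPResult:
    """Solution of the simplex QP ``min 0.5 a'Ga  s.t. a >= 0, sum a = 1``."""

    alpha: np.ndarray
    objective: float
    iterations: int
    converged: bool
    kkt_gap: float
    objective_trace: np.ndarray | None = field(default=None, repr=False)


def _check_G(G: np.ndarray, sym_tol: float = 1e-8) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"G must be square, got shape {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError("G contains non-finite entries")
    scale = max(1.0, float(np.abs(G).max()))
    if np.abs(G - G.T).max() > sym_tol * scale:
        raise ValueError("G is not symmetric within tolerance")
    return G


def smo_solve(
    G: np.ndarray,
    tol: float = 1e-6,
    max_iter: int | None = None,
    trace: bool = False,
) -> QPResult:
    """Minimize ``0.5 a'Ga`` over the probability simplex by SMO pair updates.

    Working-set selection is the maximal violating pair: ``i = argmin (Ga)_i``
    over all coordinates and ``j = argmax (Ga)_j`` over ``{j : a_j > 0}``; the
    stopping rule is ``(Ga)_j - (Ga)_i < tol``.  Each update moves mass from
    ``j`` to ``i`` by the exact 1-D minimizer on the feasible segment, so
    simplex feasibility is preserved exactly at every step and the objective is
    non-increasing.

    Parameters
    ----------
    G:
        Symmetric PSD matrix.
    tol:
        KKT violating-pair gap at which to stop.
    max_iter:
        Pair-update budget; default ``max(100 * n**2, 50_000)`` (the floor
        covers ill-conditioned small problems, where first-order pair
        selection zig-zags and needs far more than ``100 n^2`` updates).
        Exhausting it returns ``converged=False`` (logged), not an exception.
    trace:
        If True, record the objective after every update (testing aid).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    G = _check_G(G)
    n = G.shape[0]
    if max_iter is None:
        max_iter = max(100 * n * n, 50_000)
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")

    if n == 1:
        a = np.ones(1)
        return QPResult(a, 0.5 * G[0, 0], 0, True, 0.0,
                        np.asarray([0.5 * G[0, 0]]) if trace else None)

    alpha = np.full(n, 1.0 / n)
    g = G @ alpha  # gradient of the objective
    trace_vals: list[float] = []
    gap = np.inf
    converged = False
    it = 0
    while it < max_iter:
        i = int(np.argmin(g))
        # argmax of g restricted to alpha > 0
        g_active = np.where(alpha > 0, g, -np.inf)
        j = int(np.argmax(g_active))
        gap = g[j] - g[i]
        if gap < tol:
            converged = True
            break
        aj = alpha[j]
        denom = G[i, i] + G[j, j] - 2.0 * G[i, j]
        if denom > 1e-12:
            delta = min(gap / denom, aj)
        else:  # flat (semidefinite) direction: move all of alpha_j
            delta = aj
        alpha[i] += delta
        alpha[j] = aj - delta if delta < aj else 0.0  # emptied coord -> exact 0
        g += delta * (G[:, i] - G[:, j])
        it += 1
        if it % _REFRESH_EVERY == 0:
            g = G @ alpha
        if trace:
            trace_vals.append(0.5 * float(alpha @ (G @ alpha)))

    if not converged:
        logger.warning("smo_solve: max_iter=%d exhausted, kkt gap %.3e > tol %.3e", max_iter, gap, tol)
    g = G @ alpha
    objective = 0.5 * float(alpha @ g)
    final_gap = float(np.max(np.where(alpha > 0, g, -np.inf)) - np.min(g))
    return QPResult(
        alpha=alpha,
        objective=objective,
        iterations=it,
        converged=converged,
        kkt_gap=final_gap,
        objective_trace=np.asarray(trace_vals) if trace else None,
    )


def qp_oracle(G: np.ndarray, ftol: float = 1e-14, maxiter: int = 1000) -> QPResult:
    """Solve the same simplex QP with a generic smooth constrained optimizer.

    Uses SLSQP with exact gradients; intended for small problems (n <= a few
    hundred) as an independent reference for :func:`smo_solve`.
    """
    G = _check_G(G)
    n = G.shape[0]
    if n == 1:
        return QPResult(np.ones(1), 0.5 * G[0, 0], 0, True, 0.0)
    x0 = np.full(n, 1.0 / n)
    res = minimize(
        fun=lambda a: 0.5 * float(a @ (G @ a)),
        x0=x0,
        jac=lambda a: G @ a,
        bounds=[(0.0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda a: float(a.sum()) - 1.0,
                      "jac": lambda a: np.ones(n)}],
        method="SLSQP",
        options={"ftol": ftol, "maxiter": maxiter},
    )
    if not res.success:
        raise RuntimeError(f"qp_oracle failed: status {res.status}: {res.message}")
    # project onto the simplex to make the feasibility invariants exact
    alpha = np.clip(res.x, 0.0, None)
    alpha /= alpha.sum()
    g = G @ alpha
    objective = 0.5 * float(alpha @ g)
    gap = float(np.max(np.where(alpha > 1e-12, g, -np.inf)) - np.min(g))
    return QPResult(alpha=alpha, objective=objective, iterations=int(res.nit),
                    converged=True, kkt_gap=gap)


def kkt_residuals(G: np.ndarray, alpha: np.ndarray) -> dict:
    """First-order optimality residuals of a candidate simplex-QP solution.

    Returns ``feasibility_gap`` (= max of the sum-to-one violation and the
    worst negativity) and ``stationarity_gap`` (= the maximal-violating-pair
    gap: max of ``(Ga)_i`` over coordinates carrying mass minus the global min
    of ``(Ga)_i``).  Both are 0 at an exact optimum.
    """
    G = np.asarray(G, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (G.shape[0],):
        raise ValueError(f"alpha has shape {alpha.shape}, expected ({G.shape[0]},)")
    feasibility = max(abs(float(alpha.sum()) - 1.0), max(0.0, -float(alpha.min())))
    g = G @ alpha
    active = alpha > 1e-12
    if active.any():
        stationarity = float(g[active].max() - g.min())
    else:
        stationarity = np.inf
    return {"feasibility_gap": feasibility, "stationarity_gap": stationarity}
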