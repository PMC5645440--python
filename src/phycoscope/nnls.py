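"""Exact non-negative least squares for many right-hand sides.

The alternating half-steps of MCR-ALS need ``min_{K >= 0} ||A K - B||_F``
solved column-by-column for tens of thousands of columns sharing one small
design matrix ``A`` (k components, k <= ~12).  At that size the passive set
of the optimum can be found by enumeration: for every subset of variables,
solve the unconstrained normal equations restricted to the subset for all
columns at once, keep feasible candidates, and take the feasible candidate
with the lowest objective.  The optimum's own support always appears among
the subsets, so the result is exactly the NNLS solution (verified against
scipy.optimize.nnls in the test suite), while the work is fully vectorised
over columns.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nnls_multiple", "nnls_columns"]

_MAX_ENUM_K = 14


def nnls_multiple(AtA: np.ndarray, AtB: np.ndarray) -> np.ndarray:
    """Solve ``min_{K >= 0} ||A K - B||_F`` given ``A^T A`` and ``A^T B``.

    Parameters
    ----------
    AtA : (k, k) Gram matrix of the shared design.
    AtB : (k, n) cross-products, one column per right-hand side.

    Returns
    -------
    K : (k, n) non-negative solution matrix.
    """
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    k, n = AtB.shape
    if AtA.shape != (k, k):
        raise ValueError("AtA must be (k, k) matching AtB's first dimension")
    if k > _MAX_ENUM_K:
        raise ValueError(
            f"enumeration NNLS supports at most {_MAX_ENUM_K} components (got {k})"
        )

    K = np.zeros((k, n))
    # Objective relative to ||B||^2: for a subset solution satisfying its
    # normal equations, ||AK - B||^2 - ||B||^2 = -sum(K_sub * AtB_sub).
    best = np.zeros(n)  # all-zero solution
    for mask in range(1, 1 << k):
        idx = [i for i in range(k) if (mask >> i) & 1]
        sub = AtA[np.ix_(idx, idx)]
        rhs = AtB[idx]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(sub) @ rhs
        feasible = np.all(sol >= -1e-10, axis=0)
        if not feasible.any():
            continue
        obj = -np.einsum("ij,ij->j", sol, rhs)
        better = feasible & (obj < best)
        if better.any():
            best[better] = obj[better]
            K[:, better] = 0.0
            K[np.ix_(idx, np.nonzero(better)[0])] = np.clip(sol[:, better], 0.0, None)
    return K


def nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Convenience wrapper: solve ``min_{K >= 0} ||A K - B||_F`` directly."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    return nnls_multiple(A.T @ A, A.T @ B)
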