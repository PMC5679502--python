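"""Independent LP oracle: dense two-phase tableau simplex with Bland's rule.

Deliberately naive and self-contained (no scipy/GLPK) so it can serve as an
independent cross-check of the production FBA solver on small problems:

    optimise c.v  subject to  S v = 0,  l <= v <= u.

The box is converted to standard form (shifted variables plus slacks), phase
1 drives artificial variables out, phase 2 optimises the true objective.
Bland's rule guarantees termination.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-9


def _pivot(T: np.ndarray, basis: list[int], row: int, col: int) -> None:
    T[row] /= T[row, col]
    for i in range(T.shape[0]):
        if i != row and abs(T[i, col]) > 0:
            T[i] -= T[i, col] * T[row]
    basis[row] = col


def _simplex(T: np.ndarray, basis: list[int], cost: np.ndarray, allowed: np.ndarray):
    """Minimise cost over the tableau; returns the objective value."""
    m = T.shape[0]
    while True:
        # reduced costs: z_j = cost_j - cost_B . B^-1 A_j
        cb = cost[basis]
        reduced = cost - cb @ T[:, :-1]
        entering = -1
        for j in np.flatnonzero(allowed):
            if reduced[j] < -_TOL:
                entering = j  # Bland: smallest index
                break
        if entering < 0:
            return float(cb @ T[:, -1])
        ratios = np.full(m, np.inf)
        col = T[:, entering]
        for i in range(m):
            if col[i] > _TOL:
                ratios[i] = T[i, -1] / col[i]
        if not np.isfinite(ratios).any():
            return -np.inf  # unbounded
        best = np.min(ratios)
        # Bland tie-break: smallest basis index among minimal ratios
        candidates = [i for i in range(m) if ratios[i] <= best + _TOL]
        leaving = min(candidates, key=lambda i: basis[i])
        _pivot(T, basis, leaving, entering)


def reference_solve(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    maximize: bool = True,
):
    """Solve the bounded flux LP; returns (status, objective, v)."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m_eq, n = S.shape

    # x = v - lb in [0, ub - lb]; rows: S x = -S lb ; x + s = ub - lb
    width = ub - lb
    b = np.concatenate([-S @ lb, width])
    A = np.block(
        [[S, np.zeros((m_eq, n))], [np.eye(n), np.eye(n)]]
    )
    m = m_eq + n
    flip = b < 0
    A[flip] *= -1
    b[flip] *= -1

    n_total = 2 * n
    T = np.zeros((m, n_total + m + 1))
    T[:, :n_total] = A
    T[:, n_total : n_total + m] = np.eye(m)
    T[:, -1] = b
    basis = list(range(n_total, n_total + m))

    phase1_cost = np.zeros(n_total + m)
    phase1_cost[n_total:] = 1.0
    allowed = np.ones(n_total + m, dtype=bool)
    value = _simplex(T, basis, phase1_cost, allowed)
    if value > 1e-7:
        return "infeasible", np.nan, None

    # drive any still-basic artificials out of the basis (their rows are at
    # zero after a feasible phase 1; a row with no admissible pivot is
    # redundant and can be neutralised by zeroing it)
    for i in range(m):
        if basis[i] >= n_total:
            pivot_col = next(
                (j for j in range(n_total) if abs(T[i, j]) > _TOL), None
            )
            if pivot_col is not None:
                _pivot(T, basis, i, pivot_col)
            else:
                T[i, :] = 0.0
                T[i, basis[i]] = 1.0

    # phase 2: artificials must not re-enter
    allowed[n_total:] = False
    phase2_cost = np.zeros(n_total + m)
    phase2_cost[:n] = -c if maximize else c
    value = _simplex(T, basis, phase2_cost, allowed)
    if value == -np.inf:
        return "unbounded", np.nan, None

    x = np.zeros(n_total + m)
    for i, j in enumerate(basis):
        x[j] = T[i, -1]
    v = x[:n] + lb
    objective = float(c @ v)
    return "optimal", objective, v
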