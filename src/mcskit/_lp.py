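"""Thin wrappers around scipy's HiGHS LP interface.

All feasibility and optimisation questions in the package (FVA, target
validation, Farkas certification, cMCS filtering, the oracle) funnel through
these two helpers so that solver options and status handling live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: Default feasibility tolerance, matching HiGHS defaults.
FEAS_TOL = 1e-9


class LPNumericalError(RuntimeError):
    """Raised when the LP solver reports neither optimality nor infeasibility."""


@dataclass
class LPSolution:
    feasible: bool
    x: np.ndarray | None
    fun: float | None
    status: int
    message: str


def solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None) -> LPSolution:
    """Solve min c^T x subject to A_ub x <= b_ub, A_eq x = b_eq and bounds.

    ``bounds`` is a sequence of (lb, ub) pairs with ``None`` for unbounded ends.
    Unbounded problems count as feasible (``fun`` is -inf then).
    """
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 0:
        return LPSolution(True, np.asarray(res.x), float(res.fun), 0, res.message)
    if res.status == 2:  # infeasible
        return LPSolution(False, None, None, 2, res.message)
    if res.status == 3:  # unbounded => feasible
        x = np.asarray(res.x) if res.x is not None else None
        return LPSolution(True, x, -np.inf, 3, res.message)
    raise LPNumericalError(f"LP solver failure (status {res.status}): {res.message}")


def lp_feasible(A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None, n=None) -> bool:
    """Feasibility check (zero objective). ``n`` gives the variable count."""
    if n is None:
        for mat in (A_ub, A_eq):
            if mat is not None:
                n = np.asarray(mat).shape[1]
                break
        else:
            raise ValueError("cannot infer variable count")
    return solve_lp(np.zeros(n), A_ub, b_ub, A_eq, b_eq, bounds).feasible
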