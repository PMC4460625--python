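"""Brute-force vertex-enumeration LP solver used as an independent oracle.

For a feasible, bounded LP ``min c.x  s.t.  A_ub x <= b_ub, lo <= x <= hi``
the optimum is attained at a vertex, i.e. a point where some n linearly
independent constraints (inequality rows or variable bounds) hold with
equality.  Enumerating all n-subsets of constraint hyperplanes, solving each
square system and feasibility-checking the candidates is exponential but
exact, and entirely independent of any simplex/interior-point code — which is
the point.  Usable only for ~a dozen variables.
"""

import itertools

import numpy as np


def brute_force_lp(c, A_ub, b_ub, bounds, feas_tol=1e-9):
    """Return (objective, x) of the optimum by vertex enumeration."""
    c = np.asarray(c, dtype=float)
    n = c.size
    rows = [np.asarray(a, dtype=float) for a in A_ub]
    rhs = [float(b) for b in b_ub]
    for i, (lo, hi) in enumerate(bounds):
        e = np.zeros(n)
        e[i] = 1.0
        if lo is not None:
            rows.append(e.copy())
            rhs.append(float(lo))
        if hi is not None:
            rows.append(e.copy())
            rhs.append(float(hi))
    R = np.array(rows)
    r = np.array(rhs)
    A = np.asarray(A_ub, dtype=float)
    b = np.asarray(b_ub, dtype=float)

    best_obj, best_x = np.inf, None
    for combo in itertools.combinations(range(len(rows)), n):
        M = R[list(combo)]
        try:
            x = np.linalg.solve(M, r[list(combo)])
        except np.linalg.LinAlgError:
            continue
        if not np.isfinite(x).all():
            continue
        if (A @ x - b > feas_tol).any():
            continue
        ok = True
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and x[i] < lo - feas_tol:
                ok = False
                break
            if hi is not None and x[i] > hi + feas_tol:
                ok = False
                break
        if not ok:
            continue
        obj = float(c @ x)
        if obj < best_obj:
            best_obj, best_x = obj, x
    return best_obj, best_x
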