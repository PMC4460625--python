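"""Ellipsoid-separation linear program for sparse network-biomarker selection.

Each sample class k is represented by an axis-aligned ellipsoid in feature
space, centred on the class's per-feature centers.  With per-feature weights
w_i (the ellipsoid's inverse squared semi-axes, shared across classes), the
weighted squared deviation of sample j from the center of class k is

    d_jk(w) = sum_i w_i * (f_ji - fbar_ik)^2 .

The LP asks every sample of class k to lie inside an inner radius z1_k
(d_jk <= z1_k + xi_jk) and every other sample to lie outside an outer radius
z2_k (d_jk >= z2_k - xi_jk), with slack xi >= 0 tolerating data errors.  The
objective

    min  sum_edges w + lambda * sum_nodes w + alpha * sum_k (z1_k - z2_k)
         + C * sum_jk xi_jk

trades off sparsity of the selected feature set (first two terms), the
inner/outer radius gap per class (alpha rewards separation), and total
classification error (C).  All constraints are linear because the squared
deviations are precomputed constants, so a simplex/interior-point solver
returns a global optimum; the all-zeros point is always feasible.  Features
whose optimal weight exceeds a small threshold (default 1e-4) form the
biomarker set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .affinity import (
    FeatureMatrix,
    compute_differential_affinity,
    compute_ppia,
)
from .io_formats import EdgeList, ExpressionMatrix, SampleLabels

log = logging.getLogger("ppianet")

__all__ = [
    "UnboundedLPError",
    "ClassCenters",
    "EllipsoidLP",
    "LPSolution",
    "BiomarkerSet",
    "compute_class_centers",
    "build_lp",
    "solve_lp",
    "verify_solution",
    "select_features",
    "select_biomarkers",
    "grid_search",
]


class UnboundedLPError(RuntimeError):
    """Raised when a parameter cell makes the LP unbounded (see solve_lp)."""


# ---------------------------------------------------------------------------
# Class centers
# ---------------------------------------------------------------------------

@dataclass
class ClassCenters:
    """Per-class feature centers: mean or median over the class's samples."""

    edge_centers: np.ndarray  # (c, q)
    node_centers: np.ndarray  # (c, n)
    statistic: str  # "mean" or "median"

    def combined(self) -> np.ndarray:
        return np.hstack([self.edge_centers, self.node_centers])


def compute_class_centers(
    fm: FeatureMatrix, labels: SampleLabels, statistic: str = "mean"
) -> ClassCenters:
    """Center of each feature column within each class (>= 2 samples each)."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown center statistic {statistic!r}")
    reduce = np.mean if statistic == "mean" else np.median
    for cls, m_k in labels.class_sizes().items():
        if m_k < 2:
            raise ValueError(f"class {cls!r} has {m_k} sample(s); centers need >= 2")
    index_sets = labels.index_sets()
    edge_centers = np.empty((labels.n_classes, fm.q))
    node_centers = np.empty((labels.n_classes, fm.n))
    for k, cls in enumerate(labels.classes):
        rows = index_sets[cls]
        edge_centers[k] = reduce(fm.edge_features[rows], axis=0)
        node_centers[k] = reduce(fm.node_features[rows], axis=0)
    return ClassCenters(edge_centers, node_centers, statistic)


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

@dataclass
class EllipsoidLP:
    """Assembled LP in `min c.x  s.t.  A_ub x <= b_ub, bounds` form.

    Variable layout: w_1..w_{q+n}, z1_1..z1_c, z2_1..z2_c, then xi_jk in
    sample-major order (xi index = q + n + 2c + j*c + k).
    """

    objective: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    bounds: list  # (lo, hi) per variable
    q: int
    n: int
    c: int
    m: int
    lambda_: float
    alpha: float
    C: float
    edge_index: list
    node_index: list
    classes: list

    @property
    def n_vars(self) -> int:
        return self.q + self.n + 2 * self.c + self.m * self.c

    # column offsets
    def col_w(self, i: int) -> int:
        return i

    def col_z1(self, k: int) -> int:
        return self.q + self.n + k

    def col_z2(self, k: int) -> int:
        return self.q + self.n + self.c + k

    def col_xi(self, j: int, k: int) -> int:
        return self.q + self.n + 2 * self.c + j * self.c + k


def build_lp(
    fm: FeatureMatrix,
    centers: ClassCenters,
    labels: SampleLabels,
    lambda_: float = 1.0,
    alpha: float = 2.0,
    C: float = 0.1,
) -> EllipsoidLP:
    """Assemble the ellipsoid-separation LP for the given features and centers.

    Emits one inside row per (class k, sample j in I^k), one outside row per
    (class k, sample j not in I^k), and one ordering row z1_k - z2_k <= 0 per
    class; bounds are 0 <= w <= 1, z1, z2, xi >= 0.
    """
    if min(lambda_, alpha, C) <= 0:
        raise ValueError("lambda, alpha and C must all be positive")
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes: outside-ellipsoid constraints are vacuous with 1")
    if list(fm.sample_ids) != list(labels.sample_ids):
        raise ValueError("feature matrix and labels disagree on sample order")

    F = fm.combined()  # (m, p)
    G = centers.combined()  # (c, p)
    m, p = F.shape
    q, n, c = fm.q, fm.n, labels.n_classes
    lp = EllipsoidLP(
        objective=None, A_ub=None, b_ub=None, bounds=None,
        q=q, n=n, c=c, m=m, lambda_=lambda_, alpha=alpha, C=C,
        edge_index=list(fm.edge_index), node_index=list(fm.node_index),
        classes=list(labels.classes),
    )

    # squared deviations d2[k, j, i] = (F[j, i] - G[k, i])^2
    d2 = (F[None, :, :] - G[:, None, :]) ** 2

    n_rows = m + m * (c - 1) + c
    A = np.zeros((n_rows, lp.n_vars))
    b = np.zeros(n_rows)
    row = 0
    member = labels.y  # class code per sample
    for k in range(c):
        for j in range(m):
            if member[j] == k:  # inside: d_jk(w) - z1_k - xi_jk <= 0
                A[row, :p] = d2[k, j]
                A[row, lp.col_z1(k)] = -1.0
                A[row, lp.col_xi(j, k)] = -1.0
                row += 1
    for k in range(c):
        for j in range(m):
            if member[j] != k:  # outside: -d_jk(w) + z2_k - xi_jk <= 0
                A[row, :p] = -d2[k, j]
                A[row, lp.col_z2(k)] = 1.0
                A[row, lp.col_xi(j, k)] = -1.0
                row += 1
    for k in range(c):  # ordering: z1_k - z2_k <= 0
        A[row, lp.col_z1(k)] = 1.0
        A[row, lp.col_z2(k)] = -1.0
        row += 1
    assert row == n_rows

    obj = np.concatenate([
        np.ones(q),
        np.full(n, lambda_),
        np.full(c, alpha),   # z1 terms
        np.full(c, -alpha),  # z2 terms
        np.full(m * c, C),   # slack terms
    ])
    bounds = [(0.0, 1.0)] * (q + n) + [(0.0, None)] * (2 * c + m * c)

    lp.objective, lp.A_ub, lp.b_ub, lp.bounds = obj, A, b, bounds
    return lp


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

@dataclass
class LPSolution:
    w: np.ndarray  # (q + n,) in [0, 1]
    z1: np.ndarray  # (c,)
    z2: np.ndarray  # (c,)
    xi: np.ndarray  # (m, c)
    objective_value: float
    status: str

    def x(self) -> np.ndarray:
        return np.concatenate([self.w, self.z1, self.z2, self.xi.reshape(-1)])


def verify_solution(lp: EllipsoidLP, sol: LPSolution, atol: float = 1e-8, rtol: float = 1e-8):
    """Check every constraint by direct substitution; raise on violation.

    Tolerance per row is atol + rtol * (magnitude of the row's terms), so the
    check stays meaningful for both O(1) and large-valued feature data.
    """
    x = sol.x()
    lhs = lp.A_ub @ x
    scale = np.abs(lp.A_ub) @ np.abs(x)
    bad = lhs - lp.b_ub > atol + rtol * scale
    if bad.any():
        raise ValueError(
            f"LP solution violates {int(bad.sum())} constraint row(s); "
            f"worst residual {float((lhs - lp.b_ub).max()):.3e}"
        )
    for i, (lo, hi) in enumerate(lp.bounds):
        v = x[i]
        if lo is not None and v < lo - atol:
            raise ValueError(f"variable {i} below bound: {v}")
        if hi is not None and v > hi + atol:
            raise ValueError(f"variable {i} above bound: {v}")


def solve_lp(lp: EllipsoidLP, feasibility_atol: float = 1e-8) -> LPSolution:
    """Solve with HiGHS and return the unpacked, feasibility-checked solution.

    The zero vector is always feasible, so any non-optimal status signals a
    solver failure and raises.
    """
    res = linprog(
        lp.objective,
        A_ub=lp.A_ub,
        b_ub=lp.b_ub,
        bounds=lp.bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if res.status == 3:
        # alpha > C * (m - m_k) for some class: the radius reward outruns the
        # total slack penalty and z2_k can grow along a feasible ray forever
        raise UnboundedLPError(
            f"LP unbounded (alpha={lp.alpha}, C={lp.C}): the outer-radius reward "
            "exceeds the slack penalty C*(m - m_k); increase C or decrease alpha"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
    x = np.asarray(res.x, dtype=float)
    off = lp.q + lp.n
    sol = LPSolution(
        w=x[:off],
        z1=x[off: off + lp.c],
        z2=x[off + lp.c: off + 2 * lp.c],
        xi=x[off + 2 * lp.c:].reshape(lp.m, lp.c),
        objective_value=float(res.fun),
        status="optimal",
    )
    verify_solution(lp, sol, atol=feasibility_atol)
    return sol


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSet:
    selected_edges: list  # (gene_u, gene_v, weight)
    selected_nodes: list  # (gene_id, weight)
    threshold: float
    params_used: tuple  # (lambda, alpha, C)

    @property
    def n_features(self) -> int:
        return len(self.selected_edges) + len(self.selected_nodes)

    def edge_set(self) -> set:
        return {(u, v) for u, v, _ in self.selected_edges}

    def gene_set(self) -> list:
        """Union of genes in selected edges and nodes, in first-seen order."""
        genes = []
        for u, v, _ in self.selected_edges:
            for g in (u, v):
                if g not in genes:
                    genes.append(g)
        for g, _ in self.selected_nodes:
            if g not in genes:
                genes.append(g)
        return genes


def select_features(sol: LPSolution, lp: EllipsoidLP, threshold: float = 1e-4) -> BiomarkerSet:
    """Features with optimal weight strictly above ``threshold``.

    The same cut applies to edge and node weights — they share the [0, 1]
    scale.  An empty selection is returned with a warning, not an error.
    """
    edges = [
        (u, v, float(sol.w[i]))
        for i, (u, v) in enumerate(lp.edge_index)
        if sol.w[i] > threshold
    ]
    nodes = [
        (g, float(sol.w[lp.q + i]))
        for i, g in enumerate(lp.node_index)
        if sol.w[lp.q + i] > threshold
    ]
    if not edges and not nodes:
        log.warning("select_features: no weight exceeded threshold %g", threshold)
    return BiomarkerSet(edges, nodes, float(threshold), (lp.lambda_, lp.alpha, lp.C))


def select_biomarkers(
    expr: ExpressionMatrix,
    edges: EdgeList,
    labels: SampleLabels,
    form: str = "product",
    lambda_: float = 1.0,
    alpha: float = 2.0,
    C: float = 0.1,
    statistic: str = "mean",
    threshold: float = 1e-4,
):
    """Convenience pipeline: features -> centers -> LP -> thresholded set.

    Returns ``(biomarkers, fm, lp, sol)`` so callers can also inspect the LP
    diagnostics (objective, radii, total slack).
    """
    make = compute_ppia if form == "product" else compute_differential_affinity
    if form not in ("product", "differential"):
        raise ValueError(f"unknown affinity form {form!r}")
    fm = make(expr, edges)
    centers = compute_class_centers(fm, labels, statistic)
    lp = build_lp(fm, centers, labels, lambda_=lambda_, alpha=alpha, C=C)
    sol = solve_lp(lp)
    return select_features(sol, lp, threshold), fm, lp, sol


# ---------------------------------------------------------------------------
# Grid search over (alpha, C)
# ---------------------------------------------------------------------------

def grid_search(
    fm: FeatureMatrix,
    labels: SampleLabels,
    alpha_grid,
    C_grid,
    cv_scheme: str = "loo",
    n_trees: int = 500,
    seed: int = 0,
    lambda_: float = 1.0,
    statistic: str = "mean",
    threshold: float = 1e-4,
):
    """Pick (alpha, C) by cross-validated accuracy of each cell's selection.

    Every cell is scored on the same folds and classifier seed so the argmax
    reflects the selection, not fold noise.  Ties break toward the smaller
    selected set, then smaller alpha, then smaller C.  Returns
    ``(best_alpha, best_C, best_set, table)`` where ``table`` is a list of
    dicts (alpha, C, n_selected, accuracy).
    """
    from .evaluation import cross_validate  # local import: avoid module cycle

    if not len(list(alpha_grid)) or not len(list(C_grid)):
        raise ValueError("alpha_grid and C_grid must be non-empty")
    centers = compute_class_centers(fm, labels, statistic)
    X = fm.combined()
    table = []
    results = {}
    for alpha, C in itertools.product(alpha_grid, C_grid):
        lp = build_lp(fm, centers, labels, lambda_=lambda_, alpha=alpha, C=C)
        try:
            sol = solve_lp(lp)
        except UnboundedLPError:
            log.info("grid cell alpha=%g C=%g: unbounded, skipped", alpha, C)
            table.append({"alpha": alpha, "C": C, "n_selected": 0,
                          "accuracy": float("nan")})
            continue
        bset = select_features(sol, lp, threshold)
        if bset.n_features == 0:
            acc = float("nan")
        else:
            cols = [i for i in range(lp.q + lp.n) if sol.w[i] > threshold]
            report = cross_validate(X[:, cols], labels, scheme=cv_scheme,
                                    n_trees=n_trees, seed=seed)
            acc = report.accuracy
        table.append({"alpha": alpha, "C": C, "n_selected": bset.n_features,
                      "accuracy": acc})
        results[(alpha, C)] = bset
        log.info("grid cell alpha=%g C=%g: %d feature(s), accuracy=%s",
                 alpha, C, bset.n_features, acc)
    scored = [t for t in table if t["n_selected"] > 0]
    if not scored:
        raise ValueError(f"every grid cell selected zero features; table: {table}")
    best = min(scored, key=lambda t: (-t["accuracy"], t["n_selected"], t["alpha"], t["C"]))
    return best["alpha"], best["C"], results[(best["alpha"], best["C"])], table
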