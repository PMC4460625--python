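"""Cross-validated classification, redundancy scoring and univariate baselines.

Selected biomarkers are judged on two axes: predictive accuracy under
leave-one-out or stratified 10-fold cross-validation with a random-forest
classifier, and redundancy — the mean absolute Pearson correlation over all
gene pairs in the marker set (lower means the panel carries less duplicated
information).  Welch t-test (two classes) and one-way F-test (multi-class)
rankings provide the conventional single-gene baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .affinity import compute_differential_affinity, compute_ppia
from .io_formats import EdgeList, ExpressionMatrix, SampleLabels

log = logging.getLogger("ppianet")

_EPS = 1e-12  # small-denominator guard for zero-variance features

__all__ = [
    "EvaluationReport",
    "cross_validate",
    "permutation_null_accuracy",
    "redundancy_score",
    "rank_features_ttest",
    "rank_features_ftest",
    "top_k",
    "compare_methods",
    "features_for_set",
]


@dataclass
class EvaluationReport:
    accuracy: float  # fraction correct in [0, 1]
    scheme: str  # "loo" or "kfold10"
    confusion: np.ndarray  # (c, c), rows = true class in labels.classes order
    n_features: int
    classifier_seed: int
    n_fits: int = 0
    redundancy: float = field(default=float("nan"))


def _folds(scheme: str, y: np.ndarray, seed: int):
    if scheme == "loo":
        return list(LeaveOneOut().split(y.reshape(-1, 1), y))
    if scheme == "kfold10":
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        return list(skf.split(y.reshape(-1, 1), y))
    raise ValueError(f"unknown CV scheme {scheme!r}; use 'loo' or 'kfold10'")


def cross_validate(
    features: np.ndarray,
    labels: SampleLabels,
    scheme: str = "loo",
    n_trees: int = 500,
    seed: int = 0,
) -> EvaluationReport:
    """Out-of-fold accuracy of a random forest on the given feature columns.

    One forest is fitted per fold (m fits for LOO); predictions are pooled
    over all held-out samples before accuracy and the confusion matrix are
    computed.  Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = labels.y
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.size} labelled samples")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    pred = np.empty_like(y)
    n_fits = 0
    for train, test in _folds(scheme, y, seed):
        present = np.unique(y[train])
        if present.size < labels.n_classes:
            missing = [labels.classes[k] for k in range(labels.n_classes) if k not in present]
            raise ValueError(
                f"class(es) {missing} absent from a training fold "
                f"(train size {train.size}); use stratified folds or more samples"
            )
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        n_fits += 1
    conf = confusion_matrix(y, pred, labels=np.arange(labels.n_classes))
    return EvaluationReport(
        accuracy=float(np.trace(conf) / y.size),
        scheme=scheme,
        confusion=conf,
        n_features=X.shape[1],
        classifier_seed=seed,
        n_fits=n_fits,
    )


def permutation_null_accuracy(
    features: np.ndarray,
    labels: SampleLabels,
    n_permutations: int = 20,
    scheme: str = "loo",
    n_trees: int = 500,
    seed: int = 0,
) -> float:
    """Mean CV accuracy over label permutations — the chance-level control."""
    rng = np.random.default_rng(seed)
    accs = [
        cross_validate(features, labels.permuted(rng), scheme=scheme,
                       n_trees=n_trees, seed=seed).accuracy
        for _ in range(n_permutations)
    ]
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Redundancy score
# ---------------------------------------------------------------------------

def redundancy_score(expr: ExpressionMatrix, gene_set) -> float:
    """Mean |Pearson correlation| over all N = n(n-1)/2 gene pairs in the set.

    Zero-variance genes are excluded with a warning (their correlation is
    undefined); fewer than two usable genes is an error.
    """
    idx = expr.gene_index()
    genes = list(gene_set)
    if len(genes) < 2:
        raise ValueError("redundancy_score needs at least 2 genes")
    missing = [g for g in genes if g not in idx]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    rows = expr.values[[idx[g] for g in genes]]
    var = rows.var(axis=1)
    if (var == 0).any():
        dropped = [g for g, v in zip(genes, var) if v == 0]
        log.warning("redundancy_score: excluding zero-variance gene(s) %s", dropped)
        rows = rows[var > 0]
    n = rows.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(rows)
    iu = np.triu_indices(n, k=1)
    return float(np.abs(corr[iu]).mean())


# ---------------------------------------------------------------------------
# Univariate baselines
# ---------------------------------------------------------------------------

def _welch_t(x1: np.ndarray, x2: np.ndarray):
    n1, n2 = x1.size, x2.size
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x1.mean() - x2.mean()) / np.sqrt(se2 + _EPS)
    df_den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = se2**2 / (df_den + _EPS) if se2 > 0 else 1.0
    p = 2.0 * stats.t.sf(abs(t), max(df, 1.0))
    return float(t), float(p)


def _oneway_f(groups):
    m = sum(g.size for g in groups)
    c = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ss_between / (c - 1)) / (ss_within / (m - c) + _EPS)
    p = float(stats.f.sf(f, c - 1, m - c))
    return float(f), p


def _ranked(records):
    # ascending p, then larger |statistic|, then gene id — fully deterministic
    return sorted(records, key=lambda r: (r["pvalue"], -abs(r["statistic"]), r["gene_id"]))


def rank_features_ttest(expr: ExpressionMatrix, labels: SampleLabels):
    """Per-gene Welch t-test between the two classes, ranked by ascending p.

    Returns a list of dicts with keys gene_id, statistic, pvalue.
    """
    if labels.n_classes != 2:
        raise ValueError(f"t-test ranking needs exactly 2 classes, got {labels.n_classes}")
    sets = labels.index_sets()
    i1, i2 = (sets[c] for c in labels.classes)
    records = []
    for gi, g in enumerate(expr.gene_ids):
        t, p = _welch_t(expr.values[gi, i1], expr.values[gi, i2])
        records.append({"gene_id": g, "statistic": t, "pvalue": p})
    return _ranked(records)


def rank_features_ftest(expr: ExpressionMatrix, labels: SampleLabels):
    """Per-gene one-way F-test across >= 2 classes, ranked by ascending p."""
    if labels.n_classes < 2:
        raise ValueError("F-test ranking needs at least 2 classes")
    sets = [labels.index_sets()[c] for c in labels.classes]
    records = []
    for gi, g in enumerate(expr.gene_ids):
        f, p = _oneway_f([expr.values[gi, s] for s in sets])
        records.append({"gene_id": g, "statistic": f, "pvalue": p})
    return _ranked(records)


def top_k(ranked, k: int):
    """First k gene ids of a ranking."""
    return [r["gene_id"] for r in ranked[:k]]


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

def compare_methods(report_a, report_b, set_a, set_b, names=("a", "b")):
    """Side-by-side accuracy/redundancy/set-size table plus gene overlap.

    ``set_a``/``set_b`` are gene lists; overlap is the size of their
    intersection.  Returns a list of two row dicts.
    """
    overlap = len(set(set_a) & set(set_b))
    rows = []
    for name, report, genes in ((names[0], report_a, set_a), (names[1], report_b, set_b)):
        rows.append({
            "method": name,
            "accuracy": report.accuracy,
            "redundancy": report.redundancy,
            "n_genes": len(set(genes)),
            "n_common_genes": overlap,
        })
    return rows


def features_for_set(expr: ExpressionMatrix, bset, form: str = "product") -> np.ndarray:
    """Samples x features design matrix restricted to a selected biomarker set.

    Edge columns use the requested affinity form; node columns are squared
    expression, matching what the selector consumed.
    """
    edges = EdgeList([(u, v) for u, v, _ in bset.selected_edges])
    make = compute_ppia if form == "product" else compute_differential_affinity
    fm = make(expr, edges)
    cols = [fm.edge_features]
    if bset.selected_nodes:
        idx = expr.gene_index()
        rows = [idx[g] for g, _ in bset.selected_nodes]
        cols.append((expr.values[rows].T) ** 2)
    X = np.hstack(cols)
    if X.shape[1] == 0:
        raise ValueError("biomarker set is empty; nothing to evaluate")
    return X
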