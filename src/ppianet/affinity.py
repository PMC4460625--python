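"""Interaction-affinity features from expression data.

The abundance of the complex formed by interacting proteins u and v is
approximated through the law of mass action: with protein concentrations
proportional to mRNA levels and a unit affinity constant, the complex
concentration in sample i is the product x_iu * x_iv.  Each PPI edge thus
becomes one feature column ("product" form).  Single genes enter as squared
expression x_ig^2, which puts node features on the same quadratic scale as
edge products — the reason the node-weight multiplier lambda can default
to one downstream.  An alternative "differential" form |x_iu - x_iv| is
provided for comparison.

Features are deliberately NOT standardized: the downstream selector consumes
raw squared deviations from class centers, and its per-feature weights absorb
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import EdgeList, ExpressionMatrix

__all__ = [
    "FeatureMatrix",
    "compute_ppia",
    "compute_node_features",
    "compute_differential_affinity",
]


@dataclass
class FeatureMatrix:
    """Samples x features design matrix: q edge columns then n node columns."""

    sample_ids: list
    edge_features: np.ndarray  # (m, q)
    node_features: np.ndarray  # (m, n)
    edge_index: list  # q canonical (gene_u, gene_v) pairs
    node_index: list  # n gene_ids
    form: str  # "product" or "differential"

    @property
    def q(self) -> int:
        return len(self.edge_index)

    @property
    def n(self) -> int:
        return len(self.node_index)

    def combined(self) -> np.ndarray:
        """m x (q + n) matrix, edge columns first."""
        return np.hstack([self.edge_features, self.node_features])

    def feature_labels(self) -> list:
        return [f"{u}|{v}" for u, v in self.edge_index] + list(self.node_index)


def _edge_endpoint_rows(expr: ExpressionMatrix, edges: EdgeList):
    idx = expr.gene_index()
    try:
        rows_u = [idx[u] for u, _ in edges.edges]
        rows_v = [idx[v] for _, v in edges.edges]
    except KeyError as exc:
        raise ValueError(f"edge endpoint {exc.args[0]!r} absent from expression matrix") from exc
    return rows_u, rows_v

def compute_node_features(expr: ExpressionMatrix) -> np.ndarray:
    """Squared expression per gene: entry (i, g) = x_ig^2; shape (m, n)."""
    return (expr.values.T) ** 2


def compute_ppia(expr: ExpressionMatrix, edges: EdgeList) -> FeatureMatrix:
    """Product-form affinities a_ij = x_iu * x_iv plus squared node features."""
    rows_u, rows_v = _edge_endpoint_rows(expr, edges)
    edge_feat = (expr.values[rows_u] * expr.values[rows_v]).T  # (m, q)
    return FeatureMatrix(
        sample_ids=list(expr.sample_ids),
        edge_features=edge_feat,
        node_features=compute_node_features(expr),
        edge_index=list(edges.edges),
        node_index=list(expr.gene_ids),
        form="product",
    )


def compute_differential_affinity(expr: ExpressionMatrix, edges: EdgeList) -> FeatureMatrix:
    """Differential-form affinities a_ij = |x_iu - x_iv| (comparison baseline)."""
    rows_u, rows_v = _edge_endpoint_rows(expr, edges)
    edge_feat = np.abs(expr.values[rows_u] - expr.values[rows_v]).T
    return FeatureMatrix(
        sample_ids=list(expr.sample_ids),
        edge_features=edge_feat,
        node_features=compute_node_features(expr),
        edge_index=list(edges.edges),
        node_index=list(expr.gene_ids),
        form="differential",
    )
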