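"""Entropy-based low-information gene filtering and PPI edge mapping.

A gene whose expression distribution carries little information (low Shannon
entropy of its histogram across samples) is unlikely to discriminate classes
and only inflates the feature space, so it is removed before affinities are
formed.  Entropy is computed in bits over an equal-width histogram spanning
the gene's own [min, max] range; the bin count is configurable because
published analyses of this kind rarely state it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import EdgeList, ExpressionMatrix

log = logging.getLogger("ppianet")

__all__ = [
    "EntropyReport",
    "gene_entropy",
    "filter_low_information_genes",
    "map_edges_to_expression",
]


@dataclass
class EntropyReport:
    per_gene_entropy: dict  # gene_id -> entropy in bits
    threshold: float
    kept: list
    dropped: list


def gene_entropy(values, n_bins: int = 10) -> float:
    """Shannon entropy (bits) of the equal-width histogram of ``values``.

    The histogram spans [min, max] of the vector itself, so the result is
    invariant to affine rescaling.  A constant vector has entropy 0 (all mass
    in one bin); empty bins contribute nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("gene_entropy needs at least 2 values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def filter_low_information_genes(
    expr: ExpressionMatrix, threshold: float = 1.5, n_bins: int = 10
):
    """Drop genes whose histogram entropy falls below ``threshold`` bits.

    Returns the filtered :class:`ExpressionMatrix` and an
    :class:`EntropyReport`.  Keeping zero genes is fatal.
    """
    entropies = {g: gene_entropy(expr.values[i], n_bins) for i, g in enumerate(expr.gene_ids)}
    kept = [g for g in expr.gene_ids if entropies[g] >= threshold]
    dropped = [g for g in expr.gene_ids if entropies[g] < threshold]
    log.info(
        "entropy filter: kept %d / %d gene(s) at threshold %g (%d bins)",
        len(kept), expr.n_genes, threshold, n_bins,
    )
    if not kept:
        raise ValueError(f"no genes with entropy >= {threshold}; lower the threshold")
    report = EntropyReport(entropies, float(threshold), kept, dropped)
    return expr.subset_genes(kept), report


def map_edges_to_expression(edges: EdgeList, expr: ExpressionMatrix) -> EdgeList:
    """Restrict the edge list to pairs whose endpoints are both in ``expr``."""
    present = set(expr.gene_ids)
    kept = [e for e in edges.edges if e[0] in present and e[1] in present]
    log.info("edge mapping: kept %d / %d edge(s)", len(kept), len(edges.edges))
    if not kept:
        log.warning("edge mapping: no edges map into the expression matrix")
    return EdgeList(kept)
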