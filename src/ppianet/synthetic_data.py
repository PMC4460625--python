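"""Synthetic expression/PPI/label generator with planted discriminative edges.

The generator emulates the study design the selector targets: a genes x
samples intensity matrix with class structure, an interaction list, and a
small set of "planted" edges whose endpoint genes are jointly up-shifted in
one class.  Background expression is i.i.d. lognormal — guaranteeing the
non-negativity the product-form affinity requires and mimicking the
right-skew of expression intensities.  Because a planted edge boosts BOTH
endpoints by ``effect_size`` in its active class, the edge's product feature
shifts by effect_size^2 while each single gene shifts only by effect_size —
the motivating scenario where a pair discriminates more strongly than its
member genes.

With ``effect_size = 1`` the construction is an exact null: planted and
background features are identically distributed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EdgeList, ExpressionMatrix, SampleLabels, canonical_edge

log = logging.getLogger("ppianet")

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "evaluate_recovery"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the conditions used throughout the package's own
    evaluations: 200 genes, 300 interactions of which 10 are planted,
    two classes of 30 samples, a 2-fold endpoint shift (4-fold on the edge
    product) over lognormal noise with sigma = 0.5 on the log scale.
    """

    n_genes: int = 200
    n_edges: int = 300
    n_classes: int = 2
    samples_per_class: int = 30
    n_planted_edges: int = 10
    effect_size: float = 2.0  # multiplicative mean shift of planted genes in the active class
    base_mean: float = 1.0  # median background intensity (normalized linear units)
    noise_sd: float = 0.5  # sigma of log-expression
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_edges > self.n_edges:
            raise ValueError("n_planted_edges cannot exceed n_edges")
        if min(self.effect_size, self.base_mean, self.noise_sd) <= 0:
            raise ValueError("effect_size, base_mean and noise_sd must be positive")
        if self.n_classes < 2 or self.samples_per_class < 2:
            raise ValueError("need >= 2 classes with >= 2 samples each")
        if 2 * self.n_planted_edges > self.n_genes:
            raise ValueError("not enough genes for disjoint planted pairs")


@dataclass
class GroundTruth:
    planted_edges: list  # (gene_u, gene_v, active_class)
    planted_nodes: list = field(default_factory=list)

    def edge_set(self) -> set:
        return {canonical_edge(u, v) for u, v, _ in self.planted_edges}


def generate_dataset(spec: SyntheticSpec):
    """Draw one dataset; fully reproducible from ``spec.seed``.

    Returns ``(ExpressionMatrix, EdgeList, SampleLabels, GroundTruth)``.
    Planted edges pair disjoint genes; decoy edges are drawn uniformly over
    the remaining background genes (no self-loops or duplicates).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    m = spec.n_classes * spec.samples_per_class
    sample_ids = [f"S{j:03d}" for j in range(m)]
    classes = [f"class{k}" for k in range(spec.n_classes)]
    mapping = {s: classes[j // spec.samples_per_class] for j, s in enumerate(sample_ids)}
    labels = SampleLabels.from_mapping(mapping, sample_ids)

    # planted pairs over a random disjoint gene subset; the first class is the
    # unperturbed reference (control), active classes rotate over the rest
    perm = rng.permutation(spec.n_genes)
    planted = []
    for t in range(spec.n_planted_edges):
        u, v = gene_ids[perm[2 * t]], gene_ids[perm[2 * t + 1]]
        active = classes[1 + (t % (spec.n_classes - 1))]
        planted.append((*canonical_edge(u, v), active))

    # decoy edges over background genes only
    pool = perm[2 * spec.n_planted_edges:]
    n_decoys = spec.n_edges - spec.n_planted_edges
    max_pairs = math.comb(len(pool), 2)
    if n_decoys > max_pairs:
        raise ValueError(
            f"{n_decoys} decoy edges requested but only {max_pairs} background pairs exist"
        )
    decoys, seen = [], set()
    while len(decoys) < n_decoys:
        i, j = rng.choice(len(pool), size=2, replace=False)
        key = canonical_edge(gene_ids[pool[i]], gene_ids[pool[j]])
        if key not in seen:
            seen.add(key)
            decoys.append(key)

    all_edges = [canonical_edge(u, v) for u, v, _ in planted] + decoys
    order = rng.permutation(len(all_edges))
    edges = EdgeList([all_edges[i] for i in order])

    # background lognormal intensities; planted endpoints shifted in the active class
    X = rng.lognormal(mean=np.log(spec.base_mean), sigma=spec.noise_sd,
                      size=(spec.n_genes, m))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    class_cols = labels.index_sets()
    for u, v, active in planted:
        cols = class_cols[active]
        X[gidx[u], cols] *= spec.effect_size
        X[gidx[v], cols] *= spec.effect_size

    expr = ExpressionMatrix(gene_ids, sample_ids, X)
    truth = GroundTruth(planted_edges=planted)
    log.info(
        "simulate: %d genes x %d samples, %d edges (%d planted), effect %g",
        spec.n_genes, m, spec.n_edges, spec.n_planted_edges, spec.effect_size,
    )
    return expr, edges, labels, truth


def evaluate_recovery(selected, truth: GroundTruth):
    """Orientation-insensitive (precision, recall) of selected vs planted edges.

    ``selected`` is a BiomarkerSet.  With no planted edges recall is
    undefined and an error is raised; with an empty selection precision is
    reported as 0.0.
    """
    planted = truth.edge_set()
    if not planted:
        raise ValueError("no planted edges: recall is undefined")
    chosen = {canonical_edge(u, v) for u, v, _ in selected.selected_edges}
    hits = len(chosen & planted)
    recall = hits / len(planted)
    precision = hits / len(chosen) if chosen else 0.0
    return float(precision), float(recall)
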