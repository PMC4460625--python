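"""Tab-separated file formats, domain containers and run configuration.

Expression input must be **non-negative and linear-scale**: the affinity step
multiplies raw expression values, so log-ratio (possibly negative) data would
make the products sign-ambiguous.  Un-log such data before loading.
Probe-level matrices (several rows mapping to one gene) are out of scope for
the loader; collapse probes to genes beforehand, e.g. by keeping the probe
with the maximum mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("ppianet")

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "SampleLabels",
    "Config",
    "canonical_edge",
    "load_expression",
    "write_expression",
    "load_edges",
    "write_edges",
    "load_labels",
    "write_labels",
    "load_config",
]

FLOAT_FORMAT = "%.17g"  # full double precision: write/read round-trips bitwise


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative linear-scale expression values."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray  # shape (n_genes, n_samples), float64, >= 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def canonical_edge(u, v) -> tuple:
    """Orientation-insensitive edge key: lexicographically sorted pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class EdgeList:
    """Undirected protein-protein interaction pairs, canonically oriented."""

    edges: list  # list of (gene_u, gene_v), u < v

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set:
        return {g for e in self.edges for g in e}


@dataclass
class SampleLabels:
    """Class label per sample plus the per-class index sets I^k."""

    sample_ids: list
    labels: dict  # sample_id -> class label
    classes: list  # ordered distinct class labels
    y: np.ndarray = field(default=None)  # int codes aligned to sample_ids

    def __post_init__(self):
        if self.y is None:
            code = {c: k for k, c in enumerate(self.classes)}
            self.y = np.array([code[self.labels[s]] for s in self.sample_ids])

    @classmethod
    def from_mapping(cls, mapping: dict, sample_ids, min_per_class: int = 2) -> "SampleLabels":
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples without a class label: {missing[:5]}")
        classes = []
        for s in sample_ids:
            if mapping[s] not in classes:
                classes.append(mapping[s])
        out = cls(list(sample_ids), {s: mapping[s] for s in sample_ids}, classes)
        for c, m_k in out.class_sizes().items():
            if m_k < min_per_class:
                raise ValueError(f"class {c!r} has only {m_k} sample(s); need >= {min_per_class}")
        return out

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index_sets(self) -> dict:
        """I^k: sample indices per class, keyed by class label."""
        return {c: np.flatnonzero(self.y == k) for k, c in enumerate(self.classes)}

    def class_sizes(self) -> dict:
        """m_k per class."""
        return {c: int((self.y == k).sum()) for k, c in enumerate(self.classes)}

    def subset(self, sample_ids) -> "SampleLabels":
        return SampleLabels.from_mapping(self.labels, sample_ids)

    def permuted(self, rng: np.random.Generator) -> "SampleLabels":
        """Labels randomly reassigned to samples (permutation null)."""
        perm = rng.permutation(len(self.sample_ids))
        mapping = {s: self.labels[self.sample_ids[j]] for s, j in zip(self.sample_ids, perm)}
        return SampleLabels.from_mapping(mapping, self.sample_ids)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Run configuration; YAML files override these defaults key by key."""

    entropy_threshold: float = 1.5
    n_bins: int = 10
    center_statistic: str = "mean"  # or "median"
    lambda_: float = 1.0  # node-weight multiplier; 1 because node features are squared
    alpha: float = 2.0  # radius-gap reward for single runs
    C: float = 0.1  # slack penalty for single runs (soft margin)
    alpha_grid: tuple = (0.01, 0.02, 0.1, 0.5, 1.0, 5.0, 10.0)
    C_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)
    weight_threshold: float = 1e-4
    cv_scheme: str = "loo"  # or "kfold10"
    n_trees: int = 500
    classifier_seed: int = 0


def load_config(path=None, **overrides) -> Config:
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        known = set(Config.__dataclass_fields__)
        # allow the YAML spelling "lambda" for the keyword-reserved field
        if "lambda" in data:
            data["lambda_"] = data.pop("lambda")
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("alpha_grid", "C_grid"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = replace(cfg, **data)
    if overrides:
        cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
    return cfg


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def load_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample IDs, first column gene IDs).

    Rows containing missing/blank cells are dropped (count logged).  Negative
    values, duplicate gene IDs, or an empty matrix after cleaning are fatal.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except OSError as exc:
        raise ValueError(f"cannot read expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"expression file {path} has zero sample columns")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(
            f"duplicate gene IDs in {path}: {dup[:5]} — collapse probes to genes first"
        )
    df = df.apply(pd.to_numeric, errors="coerce")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        log.info("load_expression: dropped %d gene(s) with missing values", n_missing)
        df = df.dropna(axis=0)
    if df.shape[0] == 0:
        raise ValueError(f"no genes left in {path} after dropping missing-value rows")
    neg = df.lt(0).any(axis=1)
    if neg.any():
        offender = df.index[neg][0]
        raise ValueError(
            f"negative expression value in gene {offender!r}: values must be "
            "non-negative linear-scale (un-log log-ratio data first)"
        )
    return ExpressionMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy(float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Edge list I/O
# ---------------------------------------------------------------------------

def load_edges(path, expr: ExpressionMatrix) -> EdgeList:
    """Read a two-column TSV of interaction partners and filter it.

    Self-loops, duplicates (either orientation) and edges with an endpoint
    absent from ``expr`` are removed; each removal class is counted in the log.
    A malformed line (not exactly two columns) is fatal.
    """
    present = set(expr.gene_ids)
    seen, edges = set(), []
    n_loops = n_dups = n_unmapped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                n_loops += 1
                continue
            key = canonical_edge(u, v)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
            if u not in present or v not in present:
                n_unmapped += 1
                continue
            edges.append(key)
    log.info(
        "load_edges: kept %d edge(s); removed %d self-loop(s), %d duplicate(s), "
        "%d with unmapped endpoint(s)",
        len(edges), n_loops, n_dups, n_unmapped,
    )
    if not edges:
        log.warning("load_edges: no edges left after filtering %s", path)
    return EdgeList(edges)


def write_edges(edges: EdgeList, path) -> None:
    with open(path, "w") as fh:
        for u, v in edges.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Sample label I/O
# ---------------------------------------------------------------------------

def load_labels(path, expr: ExpressionMatrix) -> SampleLabels:
    """Read a two-column TSV (sample_id, class label) covering every sample."""
    mapping = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, label = parts[0].strip(), parts[1].strip()
            if sample in mapping and mapping[sample] != label:
                raise ValueError(f"{path}:{lineno}: conflicting labels for sample {sample!r}")
            mapping[sample] = label
    return SampleLabels.from_mapping(mapping, expr.sample_ids)


def write_labels(labels: SampleLabels, path) -> None:
    with open(path, "w") as fh:
        for s in labels.sample_ids:
            fh.write(f"{s}\t{labels.labels[s]}\n")
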