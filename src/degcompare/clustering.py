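"""Hierarchical clustering of experiments by their log2FC profiles.

Experiments are clustered in the space of log2 fold changes, ignoring
statistical significance.  To make profiles from heterogeneous platforms
comparable, fold changes are first normalized to the range of each
experiment (min-max to [0, 1] per column) and then standardized per gene
(zero mean, unit standard deviation per row).  Euclidean distances
between the resulting experiment columns feed Ward.D2 agglomeration,
which at each step merges the pair of clusters whose fusion minimally
increases the total within-cluster sum of squared distances to the
cluster centroids.

Optional bootstrap support resamples genes with replacement, reclusters,
and scores every internal node of the original dendrogram by the
fraction of replicates reproducing the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .profile_io import DEGListSet, MasterTable

__all__ = [
    "FeatureMatrix",
    "Dendrogram",
    "preprocess_logfc",
    "ward_cluster",
    "bootstrap_support",
]


@dataclass
class FeatureMatrix:
    """Gene x experiment matrix of normalized-standardized logFC values
    (no missing cells)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def experiments(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Agglomeration result: a SciPy linkage matrix over ``labels``.

    ``support``, when present, maps each internal node's canonical leaf
    bipartition to the bootstrap fraction reproducing it.
    """

    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset[str], float] | None = None

    def __post_init__(self) -> None:
        m = len(self.labels)
        if self.linkage.shape != (m - 1, 4):
            raise ValueError("linkage shape inconsistent with number of labels")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Cut into ``n_clusters`` flat clusters; label -> cluster id."""
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def bipartitions(self) -> list[frozenset[str]]:
        """Canonical leaf set (the side listed in the linkage row) of every
        internal node, in merge order."""
        return _node_leafsets(self.linkage, self.labels)

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths and bootstrap
        supports (when present) as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)
        leafsets = {}  # node id -> frozenset of labels

        def leafset(node) -> frozenset[str]:
            if node.id not in leafsets:
                if node.is_leaf():
                    leafsets[node.id] = frozenset([self.labels[node.id]])
                else:
                    leafsets[node.id] = leafset(node.left) | leafset(node.right)
            return leafsets[node.id]

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            inner = ",".join(
                render(child, node.dist) for child in (node.left, node.right)
            )
            label = ""
            if self.support is not None:
                sup = self.support.get(leafset(node))
                if sup is not None:
                    label = f"{sup:g}"
            return f"({inner}){label}:{length:g}"

        return render(tree, tree.dist) + ";"

    def merge_table(self) -> pd.DataFrame:
        """Linkage as a tidy table (child ids, height, cluster size)."""
        return pd.DataFrame(
            self.linkage,
            columns=["child_a", "child_b", "height", "size"],
        ).astype({"child_a": int, "child_b": int, "size": int})


def _node_leafsets(linkage: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    m = len(labels)
    sets: list[frozenset[str]] = [frozenset([lab]) for lab in labels]
    out = []
    for a, b, _, _ in linkage:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.append(merged)
    return out


def preprocess_logfc(
    master: MasterTable,
    gene_scope: str = "union-degs",
    *,
    degset: DEGListSet | None = None,
    range_method: str = "minmax",
) -> FeatureMatrix:
    """Build the normalized-standardized feature matrix.

    Steps, in fixed order: (1) restrict to genes in scope that are
    measured in every experiment; (2) per experiment column, normalize to
    the range (``minmax``: (x - min)/(max - min); alternative ``scale``:
    x/(max - min)); (3) per gene row, subtract the mean and divide by the
    standard deviation (rows with zero spread become all-zeros).

    ``gene_scope`` is ``"union-degs"`` (genes significant in at least one
    experiment; requires ``degset``) or ``"all-complete-genes"``.
    """
    if gene_scope == "union-degs":
        if degset is None:
            raise ValueError("gene_scope='union-degs' requires a degset")
        scope = [g for g in master.gene_ids if g in degset.union]
    elif gene_scope == "all-complete-genes":
        scope = list(master.gene_ids)
    else:
        raise ValueError(f"unknown gene_scope {gene_scope!r}")

    sub = master.logfc.loc[scope]
    complete = sub.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropping %d gene(s) with missing logFC in some experiment", dropped
        )
    sub = sub.loc[complete]
    if len(sub) < 2:
        raise ValueError(
            "fewer than 2 genes with complete logFC across all experiments "
            f"in scope {gene_scope!r} (missingness too high)"
        )

    vals = sub.to_numpy(dtype=float)
    col_min = vals.min(axis=0)
    col_max = vals.max(axis=0)
    span = col_max - col_min
    flat = span == 0
    if flat.any():
        bad = [sub.columns[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"constant logFC column(s), cannot range-normalize: {bad}")
    if range_method == "minmax":
        vals = (vals - col_min) / span
    elif range_method == "scale":
        vals = vals / span
    else:
        raise ValueError(f"unknown range_method {range_method!r}")

    row_mean = vals.mean(axis=1, keepdims=True)
    row_sd = vals.std(axis=1, keepdims=True)  # population SD: exact unit rows
    centered = vals - row_mean
    # values are in [0, 1] after range normalization, so an absolute
    # tolerance suffices to keep numerically-constant rows at zero
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = np.where(row_sd > 1e-9, centered / row_sd, 0.0)

    return FeatureMatrix(
        pd.DataFrame(standardized, index=sub.index, columns=sub.columns)
    )


def ward_cluster(features: FeatureMatrix) -> Dendrogram:
    """Ward.D2 agglomeration of experiments on Euclidean distances between
    feature columns.  Deterministic for fixed input (SciPy breaks distance
    ties by lowest pair index)."""
    X = features.values.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("clustering requires at least 2 experiments")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(Z, features.experiments)


def bootstrap_support(
    features: FeatureMatrix, n_boot: int = 1000, seed: int | None = None
) -> Dendrogram:
    """Ward.D2 dendrogram with gene-resampling bootstrap support.

    Genes (rows) are resampled with replacement ``n_boot`` times and the
    experiments reclustered; each internal node of the original tree is
    scored by the fraction of replicate trees containing the same leaf
    bipartition.  Experiments — the objects under study — are never
    resampled.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = ward_cluster(features)
    targets = [_canonical(s, base.labels) for s in base.bipartitions()]
    hits = np.zeros(len(targets))
    rng = np.random.default_rng(seed)
    vals = features.values.to_numpy(dtype=float)
    n_genes = vals.shape[0]
    for _ in range(n_boot):
        rows = rng.integers(0, n_genes, size=n_genes)
        Z = hierarchy.linkage(vals[rows].T, method="ward")
        rep = {
            _canonical(s, base.labels)
            for s in _node_leafsets(Z, base.labels)
        }
        for i, t in enumerate(targets):
            if t in rep:
                hits[i] += 1
    support = {
        s: float(h / n_boot) for s, h in zip(base.bipartitions(), hits)
    }
    return Dendrogram(base.linkage, base.labels, support)


def _canonical(leafset: frozenset[str], labels: Iterable[str]) -> frozenset[str]:
    """Bipartition identity: a node's leaf set or its complement, whichever
    is smaller (ties by sorted contents), so mirrored trees compare equal."""
    comp = frozenset(labels) - leafset
    if len(leafset) != len(comp):
        return leafset if len(leafset) < len(comp) else comp
    return min(leafset, comp, key=lambda s: tuple(sorted(s)))
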