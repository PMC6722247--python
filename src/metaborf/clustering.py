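"""Agglomerative hierarchical clustering of profiles and correlation structure.

Two dendrograms are built for the refined profile, both with average
linkage (UPGMA):

* the **data matrix** — metabolites (and, separately, subjects) of the
  log-transformed abundance matrix, with Spearman distance
  ``1 - rank correlation`` so monotone association drives the grouping
  and outliers cannot dominate;
* the **correlation matrix** — rows of the metabolite Pearson-correlation
  matrix, with correlation distance. By default each row is treated as a
  metabolite's correlation *profile* and the distance is one minus the
  Pearson correlation of two profiles; ``1 - r`` applied directly to the
  pairwise correlations is available via ``mode="direct"``.

Flat clusters are read off by cutting all merges above a linkage
threshold; both the total cluster count and the number of multimember
clusters are reported, since singletons are usually not lettered on a
heatmap dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


@dataclass
class DendrogramResult:
    """An average-linkage tree over named items."""

    item_ids: list[str]
    linkage: np.ndarray  # scipy (n-1) x 4 merge table
    cophenetic: np.ndarray  # condensed item-pair cophenetic heights

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def cophenetic_matrix(self) -> pd.DataFrame:
        m = squareform(self.cophenetic)
        return pd.DataFrame(m, index=self.item_ids, columns=self.item_ids)

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick serialization; branch lengths are half the merge-height
        differences, so the path length between two leaves equals their
        cophenetic height (ultrametric tree)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            branch = max(parent_height - node.dist, 0.0) / 2.0
            if node.is_leaf():
                return f"{self.item_ids[node.id]}:{branch:.10g}"
            children = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{branch:.10g}"

        if tree.is_leaf():
            nwk = f"{self.item_ids[tree.id]};"
        else:
            nwk = "(" + ",".join(
                walk(c, tree.dist) for c in (tree.left, tree.right)
            ) + ");"
        if path is not None:
            Path(path).write_text(nwk + "\n", encoding="utf-8")
        return nwk


@dataclass
class FlatClusters:
    """Flat clusters from cutting a dendrogram at a linkage threshold."""

    threshold: float
    assignments: pd.Series  # item id -> cluster label (1-based ints)
    n_clusters: int
    n_multimember: int

    def members(self, label: int) -> list[str]:
        return list(self.assignments.index[self.assignments == label])

    def to_tsv(self, path: str | Path) -> None:
        out = self.assignments.rename("cluster").to_frame()
        out.index.name = "item_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def spearman_distance_matrix(x_log) -> pd.DataFrame:
    """Pairwise 1 - Spearman rank correlation between item rows.

    Ties receive average ranks. A constant item has no defined rank
    correlation and is reported as an error by name.
    """
    X, ids = _as_items_matrix(x_log)
    if X.shape[1] < 3:
        raise ValueError("spearman distance requires >= 3 observations per item")
    const = np.flatnonzero(X.std(axis=1) == 0)
    if const.size:
        raise ValueError(f"constant item {ids[int(const[0])]!r}: Spearman correlation undefined")
    ranks = np.apply_along_axis(rankdata, 1, X)
    d = 1.0 - np.corrcoef(ranks)
    return _distance_frame(d, ids)


def correlation_distance_matrix(x, mode: str = "profile") -> pd.DataFrame:
    """Distances for clustering the metabolite correlation matrix.

    ``mode="profile"`` (default): Pearson correlation matrix of the items
    is computed, and the distance between items i and j is 1 minus the
    Pearson correlation of their correlation *rows* — clustering the
    correlation matrix itself. ``mode="direct"``: 1 - r_ij straight from
    the pairwise correlations.
    """
    X, ids = _as_items_matrix(x)
    if X.shape[1] < 3:
        raise ValueError("correlation distance requires >= 3 observations per item")
    const = np.flatnonzero(X.std(axis=1) == 0)
    if const.size:
        raise ValueError(f"zero-variance item {ids[int(const[0])]!r}")
    R = np.corrcoef(X)
    if mode == "direct":
        d = 1.0 - R
    elif mode == "profile":
        prof_sd = R.std(axis=1)
        if np.any(prof_sd == 0):
            j = int(np.flatnonzero(prof_sd == 0)[0])
            raise ValueError(f"item {ids[j]!r} has a zero-variance correlation profile")
        d = 1.0 - np.corrcoef(R)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _distance_frame(d, ids)


def _as_items_matrix(x):
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    X = np.asarray(x, dtype=float)
    return X, [f"item{i}" for i in range(X.shape[0])]


def _distance_frame(d: np.ndarray, ids: list[str]) -> pd.DataFrame:
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away fp noise
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# linkage and cuts
# ---------------------------------------------------------------------------

def average_linkage(d) -> DendrogramResult:
    """UPGMA agglomeration of a symmetric, zero-diagonal distance matrix.

    Repeatedly merges the two clusters with minimal mean inter-cluster
    distance; merge heights are non-decreasing (average linkage is
    monotone).
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        ids = [f"item{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    condensed = squareform(np.ascontiguousarray((D + D.T) / 2.0), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    coph = hierarchy.cophenet(Z)
    return DendrogramResult(item_ids=ids, linkage=Z, cophenetic=coph)


def cut_at_threshold(dend: DendrogramResult, threshold: float) -> FlatClusters:
    """Flat clusters = connected components after removing merges above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    labels = hierarchy.fcluster(dend.linkage, t=threshold, criterion="distance")
    assignments = pd.Series(labels, index=dend.item_ids, name="cluster")
    counts = assignments.value_counts()
    return FlatClusters(
        threshold=threshold,
        assignments=assignments,
        n_clusters=int(counts.size),
        n_multimember=int((counts >= 2).sum()),
    )


def cut_into_k(dend: DendrogramResult, k: int) -> FlatClusters:
    """Cut into exactly k clusters (maxclust criterion); used for recovery tests."""
    labels = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=dend.item_ids, name="cluster")
    counts = assignments.value_counts()
    return FlatClusters(
        threshold=float("nan"), assignments=assignments,
        n_clusters=int(counts.size), n_multimember=int((counts >= 2).sum()),
    )


def cluster_both_axes(x_log) -> tuple[DendrogramResult, DendrogramResult]:
    """Spearman/average-linkage dendrograms for rows (metabolites) and columns (subjects).

    ``x_log`` is a metabolites x subjects log-abundance DataFrame; the
    returned pair orders a heatmap on both axes.
    """
    if not isinstance(x_log, pd.DataFrame):
        x_log = pd.DataFrame(np.asarray(x_log, dtype=float))
    row_d = spearman_distance_matrix(x_log)
    col_d = spearman_distance_matrix(x_log.T)
    return average_linkage(row_d), average_linkage(col_d)
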