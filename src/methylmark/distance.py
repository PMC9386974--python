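"""Euclidean sample distances on DMR region methylation and hierarchical clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .dmr import DMR
from .markers import region_mean_methylation, smooth_profile
from .methylome_io import MethylMatrix

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("complete", "single", "average", "ward")


@dataclass
class DistanceMatrix:
    samples: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.samples), len(self.samples)):
            raise ValueError("distance matrix shape must be n_samples x n_samples")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment when the tree is cut into k groups."""
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def region_mean_matrix(
    regions: list[tuple[str, int, int]],
    matrix: MethylMatrix,
    smooth_bandwidth: int | None = None,
) -> pd.DataFrame:
    """Samples x regions matrix of region-mean methylation.

    With ``smooth_bandwidth`` the per-CpG levels are kernel-smoothed inside
    each region before averaging (the smoothed-value mode used for distance
    heatmaps); without it raw region means are used.
    """
    columns = {}
    for chrom, start, end in regions:
        key = f"{chrom}:{start}-{end}"
        if smooth_bandwidth is not None:
            try:
                prof = smooth_profile(matrix, chrom, start, end, bandwidth=smooth_bandwidth)
            except ValueError:
                columns[key] = [np.nan] * len(matrix.samples)
                continue
            columns[key] = prof.values.mean(axis=1, skipna=True).tolist()
        else:
            columns[key] = [
                region_mean_methylation(matrix, s, chrom, start, end)
                for s in matrix.samples
            ]
    return pd.DataFrame(columns, index=matrix.samples)


def unique_spans(tables: dict[tuple[str, str], list[DMR]]) -> list[tuple[str, int, int]]:
    """Sorted unique DMR spans pooled over all pairwise tables."""
    spans = {d.span for dmrs in tables.values() for d in dmrs}
    return sorted(spans)


def top_variable_dmrs(region_means: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """The n regions with the highest across-sample variance of region means.

    Duplicate columns (identical spans emitted by different comparisons) are
    merged first; if fewer than n regions exist, all are returned with a
    logged notice.  Ranking uses population variance with NaNs skipped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if region_means.shape[1] == 0:
        raise ValueError("empty region matrix")
    deduped = region_means.loc[:, ~region_means.columns.duplicated()]
    variances = deduped.var(axis=0, ddof=0, skipna=True)
    order = variances.sort_values(ascending=False, kind="mergesort")
    if len(order) < n:
        logger.info("only %d regions available (requested %d)", len(order), n)
    keep = order.index[:n]
    return deduped.loc[:, keep]


def euclidean_distances(region_means: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between sample rows; missing entries imputed
    with the region's across-sample mean (regions missing everywhere are
    dropped)."""
    if region_means.shape[0] < 2:
        raise ValueError("need at least two samples")
    values = region_means.to_numpy(dtype=float)
    col_means = np.nanmean(
        np.where(np.isnan(values).all(axis=0), 0.0, values), axis=0
    )
    all_nan = np.isnan(values).all(axis=0)
    values = values[:, ~all_nan]
    col_means = col_means[~all_nan]
    values = np.where(np.isnan(values), col_means[None, :], values)
    condensed = pdist(values, metric="euclidean")
    return DistanceMatrix(list(region_means.index), squareform(condensed))


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of samples from a precomputed distance matrix."""
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    condensed = squareform(dist.matrix, checks=True)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(labels=list(dist.samples), linkage_matrix=Z, method=linkage)
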