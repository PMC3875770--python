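"""Cohort stratification: row standardisation, hierarchical clustering
with reproducible leaf ordering, order propagation across linked heat
maps, quantile expression tracks, a PCA batch check, and the random
gene-set clustering-stability control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .matrices import ExprMatrix, MethMatrix

__all__ = [
    "ClusteredView",
    "row_standardize",
    "hierarchical_order",
    "cluster_view",
    "cut_clusters",
    "propagate_order",
    "quantile_track",
    "pca_batch_check",
    "random_signature_control",
]

log = logging.getLogger(__name__)


@dataclass
class ClusteredView:
    """A clustered heat-map view: the standardized matrix, the leaf
    permutations for both axes, and the linkage trees behind them."""

    matrix: pd.DataFrame
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def row_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, SD 1 (ddof=1) over its
    unmasked entries. Rows with zero variance or fewer than 2 values
    are dropped, logged."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    n = matrix.notna().sum(axis=1)
    ok = (n >= 2) & (sd > 0)
    dropped = int((~ok).sum())
    if dropped:
        log.info("row_standardize: dropped %d zero-variance/short rows", dropped)
    kept = matrix.loc[ok]
    return kept.sub(mean[ok], axis=0).div(sd[ok], axis=0)


def _pairwise_complete_euclidean(x: np.ndarray, labels) -> np.ndarray:
    """Condensed Euclidean distances using pairwise-complete entries,
    rescaled by the fraction of complete coordinates so sparsely
    overlapping pairs stay comparable."""
    n, p = x.shape
    finite = np.isfinite(x)
    if finite.all():
        from scipy.spatial.distance import pdist
        return pdist(x, metric="euclidean")
    xz = np.where(finite, x, 0.0)
    f = finite.astype(float)
    sq = xz ** 2
    # sum over jointly complete coords of (xi - xj)^2
    cross = xz @ xz.T
    si = sq @ f.T
    ssd = si + si.T - 2 * cross
    counts = f @ f.T
    bad = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
           if counts[i, j] == 0]
    if bad:
        raise ValueError(f"no jointly unmasked coordinates for item pairs: {bad[:5]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(ssd, 0.0) * (p / counts))
    iu = np.triu_indices(n, k=1)
    return d[iu]


def _reorder_leaves(linkage: np.ndarray, leaf_values: np.ndarray) -> list[int]:
    """Dendrogram leaf order with each node's children sorted by
    ascending subtree mean of ``leaf_values``; ties keep input order.
    Mirrors the weighted dendrogram reordering used by standard
    heat-map tools, making orders reproducible."""
    n = len(leaf_values)
    if n == 1:
        return [0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    means: dict[int, float] = {i: float(leaf_values[i]) for i in range(n)}
    for k, (a, b, _, _) in enumerate(linkage):
        a, b = int(a), int(b)
        first, second = (a, b) if means[a] <= means[b] else (b, a)
        members[n + k] = members[first] + members[second]
        means[n + k] = float(np.mean([leaf_values[i] for i in members[n + k]]))
    return members[n + len(linkage) - 1]


def hierarchical_order(matrix: pd.DataFrame, axis: str = "columns",
                       ) -> tuple[list, np.ndarray]:
    """Complete-linkage hierarchical clustering with Euclidean distance
    along one axis; returns the reordered labels and the linkage.

    Distances over masked data are pairwise-complete, rescaled by the
    fraction of shared coordinates. Leaves are ordered by subtree mean.
    """
    if axis in ("columns", "cols", 1):
        data = matrix.T
    elif axis in ("rows", "index", 0):
        data = matrix
    else:
        raise ValueError(f"unknown axis {axis!r}")
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    x = data.to_numpy(dtype=float)
    d = _pairwise_complete_euclidean(x, labels)
    link = hierarchy.linkage(d, method="complete")
    leaf_values = np.array([np.nanmean(row) if np.isfinite(row).any() else 0.0
                            for row in x])
    order = _reorder_leaves(link, leaf_values)
    return [labels[i] for i in order], link


def cluster_view(matrix: pd.DataFrame, cluster_on: str = "scaled") -> ClusteredView:
    """Row-standardize and cluster both axes of a gene × sample matrix.

    ``cluster_on='scaled'`` clusters the standardized values (the
    displayed matrix); ``'raw'`` clusters the input values while still
    standardizing the display.
    """
    scaled = row_standardize(matrix)
    basis = scaled if cluster_on == "scaled" else matrix.loc[scaled.index]
    row_order, row_link = hierarchical_order(basis, axis="rows")
    col_order, col_link = hierarchical_order(basis, axis="columns")
    return ClusteredView(scaled, row_order, col_order, row_link, col_link)


def cut_clusters(linkage: np.ndarray, labels: list, k: int = 2) -> pd.Series:
    """Flat cluster labels (1..k) from a linkage tree."""
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(flat, index=labels)


def propagate_order(view: ClusteredView,
                    others: dict[str, pd.DataFrame],
                    tss_distances: dict[str, pd.Series] | None = None,
                    ) -> dict[str, pd.DataFrame]:
    """Reindex companion matrices to the view's sample (column) order
    so stacked heat maps stay aligned.

    Matrices named in ``tss_distances`` are methylation panels: their
    rows are additionally sorted by ascending signed distance to the
    TSS (upstream probes first).
    """
    tss_distances = tss_distances or {}
    out = {}
    for name, mat in others.items():
        missing = [s for s in view.col_order if s not in mat.columns]
        if missing:
            raise KeyError(f"matrix {name!r} lacks samples {missing}")
        ordered = mat[view.col_order]
        if name in tss_distances:
            dist = tss_distances[name].reindex(ordered.index)
            ordered = ordered.loc[dist.sort_values(kind="stable").index]
        out[name] = ordered
    return out


def quantile_track(values: pd.Series, k: int = 5) -> pd.Series:
    """Equal-frequency interval labels 1..k per sample (1 = lowest
    fifth when k=5). Masked entries stay missing; a track needs at
    least k unmasked values. Heavy ties can collapse intervals, logged."""
    obs = values.dropna()
    if len(obs) < k:
        log.warning("quantile_track: fewer than k=%d values; track missing", k)
        return pd.Series(np.nan, index=values.index)
    from scipy.stats import rankdata
    r = rankdata(obs.to_numpy())
    labels = np.ceil(r * k / len(obs)).astype(int)
    if len(np.unique(labels)) < k:
        log.warning("quantile_track: ties collapsed %d interval(s)",
                    k - len(np.unique(labels)))
    out = pd.Series(np.nan, index=values.index)
    out.loc[obs.index] = labels
    return out


def pca_batch_check(mvalues: MethMatrix, annotation: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of the samples over filtered
    probes, for batch-effect assessment.

    Sex-chromosome and SNP-flagged probes and probes with any masked
    value are removed before the PCA. Returns per-sample PC1/PC2
    coordinates and the explained-variance fractions.
    """
    vals = mvalues.values
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for a batch check")
    ann = annotation.reindex(vals.index)
    chrom = ann["chrom"].astype(str).str.lower().str.removeprefix("chr")
    keep = (~chrom.isin(("x", "y"))) & (~ann["snp_flag"].astype(bool).fillna(True))
    sub = vals.loc[keep.to_numpy(dtype=bool)].dropna(axis=0, how="any")
    if len(sub) < 3:
        raise ValueError("fewer than 3 complete probes after filtering")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(sub.to_numpy(dtype=float).T)
    return (pd.DataFrame(coords, index=vals.columns, columns=["PC1", "PC2"]),
            pca.explained_variance_ratio_)


def random_signature_control(expr: ExprMatrix | pd.DataFrame,
                             signature_genes: list[str],
                             k: int = 25,
                             n_draws: int = 100,
                             seed: int = 0,
                             cluster_on: str = "scaled") -> dict:
    """Clustering-stability control with random gene sets.

    Samples are partitioned (2 clusters, complete linkage) once on the
    signature genes and then on ``n_draws`` random sets of ``k`` genes;
    the adjusted Rand index between each random partition and the
    signature partition measures whether the signature's stratification
    could arise from arbitrary genes.
    """
    vals = expr.values if isinstance(expr, ExprMatrix) else expr
    genes = [g for g in signature_genes if g in vals.index]
    if len(vals.index) < k:
        raise ValueError(f"need at least k={k} genes")
    if len(genes) < 2:
        raise ValueError("signature has fewer than 2 genes present in the matrix")
    rng = np.random.default_rng(seed)

    def partition(gene_subset) -> pd.Series:
        sub = row_standardize(vals.loc[gene_subset])
        basis = sub if cluster_on == "scaled" else vals.loc[sub.index]
        _, link = hierarchical_order(basis, axis="columns")
        return cut_clusters(link, list(vals.columns), k=2)

    sig_part = partition(genes)
    all_genes = np.asarray(vals.index)
    aris = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(all_genes, size=k, replace=False)
        aris[i] = adjusted_rand_score(sig_part, partition(list(draw)))
    return {
        "signature_partition": sig_part,
        "ari_per_draw": aris,
        "mean_ari": float(aris.mean()),
        "max_ari": float(aris.max()),
    }
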