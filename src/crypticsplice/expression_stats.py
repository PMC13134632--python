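"""Gene-expression normalisation, differential expression, PCA and clustering.

Counts are normalised as RPKM (reads per kilobase of exon model per million
assigned reads), log2-transformed with a pseudocount, and quantile-normalised
at the sample level so every sample shares one value distribution.
Differential expression uses a per-gene two-sided t-test (pooled-variance
Student by default here, Welch switchable) with Benjamini-Hochberg
correction. PCA treats samples as observations of centred (not scaled)
features; hierarchical clustering is agglomerative on Euclidean distances
with complete linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .splicing_stats import _two_sided_t, bh_adjust


def filter_low_depth_genes(counts: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Keep genes whose mean count across samples is >= ``min_mean``."""
    return counts[counts.mean(axis=1) >= min_mean]


def counts_to_rpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = count / (gene length in kb) / (library size in millions).

    ``library_sizes`` defaults to the per-sample column sums of ``counts``.
    """
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise KeyError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1_000.0, axis=0).div(lib / 1_000_000.0, axis=1)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount)."""
    return np.log2(matrix + pseudocount)


def quantile_normalize(matrix: pd.DataFrame, ties: str = "average") -> pd.DataFrame:
    """Classic sample-level quantile normalisation.

    Each sample column is replaced by the across-sample mean of the sorted
    columns, mapped back through the column's ranks. Two tie policies:

    - ``ties="average"``: tied values receive the mean of the reference
      values they would have occupied. On tie-free data every column then
      has an identical sorted value vector and the operation is idempotent;
      with ties, the averaging perturbs the shared distribution slightly.
    - ``ties="first"``: ties are broken by row order, so every column is an
      exact permutation of the reference vector — identical sorted columns
      and exact idempotence even with ties (at the cost of an arbitrary but
      deterministic ordering among tied values).
    """
    values = matrix.to_numpy(dtype=float)
    n, _ = values.shape
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        if ties == "average":
            ranks = stats.rankdata(values[:, j], method="average")
            out[:, j] = np.interp(ranks - 1.0, np.arange(n), sorted_means)
        elif ties == "first":
            ranks = stats.rankdata(values[:, j], method="ordinal")
            out[:, j] = sorted_means[ranks - 1]
        else:
            raise ValueError(f"unknown tie policy {ties!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_expression(
    counts: pd.DataFrame,
    gene_lengths,
    min_mean: float = 1.0,
    pseudocount: float = 1.0,
    ties: str = "first",
) -> pd.DataFrame:
    """Full normalisation chain: depth filter -> RPKM -> log2 -> quantile.

    The chain uses order-stable tie handling (``ties="first"``) so the
    normalised matrix keeps the defining quantile-normalisation property —
    identical sorted columns, exact idempotence — even when integer counts
    produce tied log2-RPKM values.
    """
    filtered = filter_low_depth_genes(counts, min_mean)
    rpkm = counts_to_rpkm(filtered, gene_lengths)
    return quantile_normalize(log2_transform(rpkm, pseudocount), ties=ties)


@dataclass
class DEResult:
    gene: str
    group_means: dict[str, float]
    log_diff: float
    p_value: float
    q_value: float


def differential_expression(
    norm_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    welch: bool = False,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided t-test on the normalised matrix, BH-adjusted.

    Returns a DataFrame with group means, ``log_diff`` (a - b), ``p``, ``q``
    and a ``significant`` flag (q < ``q_max``).
    """
    sa = [s for s in norm_matrix.columns if groups.get(s) == group_a]
    sb = [s for s in norm_matrix.columns if groups.get(s) == group_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need at least two samples per group")
    a = norm_matrix[sa].to_numpy(dtype=float)
    b = norm_matrix[sb].to_numpy(dtype=float)
    p = np.array([_two_sided_t(a[i], b[i], welch) for i in range(a.shape[0])])
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            f"mean_{group_a}": a.mean(axis=1),
            f"mean_{group_b}": b.mean(axis=1),
            "log_diff": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
            "q_value": q,
            "significant": q < q_max,
        },
        index=norm_matrix.index,
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component
    variance_fraction: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of a feature x sample matrix; samples are the observations.

    Features are centred, not scaled; components come from SVD.
    """
    x = matrix.to_numpy(dtype=float).T  # samples as rows
    k = n_components or min(x.shape)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(
            model.components_.T, index=matrix.index, columns=comp_names
        ),
        variance_fraction=model.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]  # column labels in input order
    leaves: list[str]  # deterministic dendrogram leaf order

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` flat clusters; returns label -> cluster id."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of the samples (columns), Euclidean metric."""
    x = matrix.to_numpy(dtype=float).T
    link = hierarchy.linkage(x, method=method, metric="euclidean")
    order = hierarchy.leaves_list(link)
    labels = list(matrix.columns)
    return ClusterResult(linkage=link, labels=labels,
                         leaves=[labels[i] for i in order])


def dendrogram_newick(result: ClusterResult) -> str:
    """Serialise the sample dendrogram as a Newick-like nested string."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return result.labels[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"
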