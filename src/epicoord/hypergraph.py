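"""Hypergraph construction from DMP x CpG correlation structure.

Vertices are DMPs; every other CpG can define a hyperedge.  The bipartite
Pearson correlation matrix between DMPs and background CpGs (computed
within one group's samples) is binarized at a cutoff equal to the sample
standard deviation of its |r| entries, giving the hypergraph incidence
matrix M.  The adjacency A = M . M^t counts, for each pair of DMPs, the
CpG correlations they share (the pair's hyperedge dimension).  A central
cluster of highly coordinated DMPs is refined by hierarchical clustering
of adjacency rows, and peripheral CpGs are those associated with more than
95% of the cluster's DMPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import CentralCluster, IncidenceMatrix, MethylationDataset

logger = logging.getLogger(__name__)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Rows to mean 0 / SD 1 (ddof=1); constant rows set to 0.  Returns count."""
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant] = 1.0
    Z = (X - mean) / sd
    Z[constant] = 0.0
    return Z, int(constant.sum())


def row_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of X and every row of Y (same columns).

    Constant rows yield correlation 0.
    """
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least three samples to correlate")
    Zx, cx = _standardize_rows(np.asarray(X, dtype=float))
    Zy, cy = _standardize_rows(np.asarray(Y, dtype=float))
    if cx or cy:
        logger.info("row_correlation zeroed %d constant rows", cx + cy)
    R = (Zx @ Zy.T) / (n - 1)
    return np.clip(R, -1.0, 1.0)


def bipartite_correlation(
    dataset: MethylationDataset,
    dmp_ids,
    group: str | None = None,
    background_ids=None,
) -> pd.DataFrame:
    """DMP x background-CpG Pearson correlations within one group's samples.

    ``background_ids`` defaults to all probes not in ``dmp_ids``; it may be
    capped by the caller for tractability.  If ``group`` is None the
    dataset is assumed to be already restricted to one group.
    """
    ds = dataset.restrict_group(group) if group is not None else dataset
    if ds.n_samples < 3:
        raise ValueError("group has fewer than three samples")
    dmp_ids = [p for p in dmp_ids if p in ds.probe_ids]
    if not dmp_ids:
        raise ValueError("no dmp_ids present in dataset")
    if background_ids is None:
        background_ids = ds.probe_ids.difference(dmp_ids).sort_values()
    else:
        background_ids = pd.Index(background_ids)
        overlap = background_ids.intersection(pd.Index(dmp_ids))
        if len(overlap):
            raise ValueError("background_ids overlap dmp_ids")
    X = ds.values.loc[dmp_ids].to_numpy(dtype=float)
    Y = ds.values.loc[background_ids].to_numpy(dtype=float)
    R = row_correlation(X, Y)
    return pd.DataFrame(R, index=pd.Index(dmp_ids), columns=background_ids)


def binarize_incidence(R: pd.DataFrame) -> IncidenceMatrix:
    """Binarize |r| at a cutoff equal to the pooled sample SD of |r| entries.

    An entry is retained iff ``|r| > t`` (strict), so only the larger
    positive or negative correlations survive.
    """
    if R.size == 0:
        raise ValueError("empty correlation matrix")
    absr = np.abs(R.to_numpy(dtype=float))
    t = float(absr.std(ddof=1))
    if t == 0:
        raise ValueError("degenerate correlation structure: SD of |r| is zero")
    M = (absr > t).astype(np.int8)
    return IncidenceMatrix(
        values=pd.DataFrame(M, index=R.index, columns=R.columns),
        threshold_used=t,
    )


def adjacency_from_incidence(M: IncidenceMatrix) -> pd.DataFrame:
    """Hypergraph adjacency A = M . M^t (shared-correlation counts)."""
    B = M.values.to_numpy(dtype=np.int64)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    A = B @ B.T
    return pd.DataFrame(A, index=M.values.index, columns=M.values.index)


def extract_central_cluster(
    A: pd.DataFrame, min_size: int = 10, k_max: int = 20
) -> CentralCluster:
    """Refine the primary cluster of DMPs connected by high-dimension hyperedges.

    Average-linkage hierarchical clustering on Euclidean distances between
    adjacency rows.  The tree is cut scanning k = 2..k_max; at each cut the
    cluster with the highest mean internal off-diagonal edge dimension is
    identified, and the scan stops at the smallest k for which that
    maximizing cluster has size >= ``min_size``.  If the off-diagonal
    structure is perfectly uniform there is nothing to refine and the full
    vertex set is returned.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    ids = list(A.index)
    n = len(ids)
    if n < min_size:
        raise ValueError(
            f"only {n} vertices; no cluster can reach min_size={min_size}; "
            "try a smaller min_size"
        )
    arr = A.to_numpy(dtype=float)
    off = arr[~np.eye(n, dtype=bool)]
    if n < 3 or np.allclose(off, off[0] if len(off) else 0.0):
        # degenerate: no structure to refine
        mean_dim = float(off.mean()) if len(off) else 0.0
        return CentralCluster(members=ids, n_clusters_cut=1,
                              mean_internal_dimension=mean_dim)
    Z = linkage(arr, method="average", metric="euclidean")
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        best_score, best_members = -np.inf, None
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) < 2:
                continue
            sub = arr[np.ix_(members, members)]
            score = float(sub[~np.eye(len(members), dtype=bool)].mean())
            if score > best_score:
                best_score, best_members = score, members
        if best_members is not None and len(best_members) >= min_size:
            return CentralCluster(
                members=[ids[i] for i in best_members],
                n_clusters_cut=k,
                mean_internal_dimension=best_score,
            )
    raise ValueError(
        f"no cut yields a maximizing cluster of size >= {min_size}; "
        "try a smaller min_size"
    )


def refine_peripheral_cpgs(
    M: IncidenceMatrix, cluster: CentralCluster, fraction: float = 0.95
) -> list:
    """CpGs associated with strictly more than ``fraction`` of cluster DMPs."""
    if not cluster.members:
        raise ValueError("empty central cluster")
    sub = M.values.loc[cluster.members]
    share = sub.to_numpy().sum(axis=0) / len(cluster.members)
    return list(M.values.columns[share > fraction])


def compare_clusters(set_a, set_b) -> dict:
    """Exact overlap summary of two DMP sets."""
    a, b = set(set_a), set(set_b)
    shared = a & b
    union = a | b
    return {
        "shared": len(shared),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
        "jaccard": len(shared) / len(union) if union else 0.0,
    }


def peripheral_strength_comparison(
    R_a: pd.DataFrame,
    M_a: IncidenceMatrix,
    cluster_a: CentralCluster,
    R_b: pd.DataFrame,
    M_b: IncidenceMatrix,
    cluster_b: CentralCluster,
) -> dict:
    """Compare |r| of hyperedge-defining (DMP, CpG) pairs between two groups.

    Collects |r| over incidence-retained pairs restricted to each group's
    central cluster, and reports the medians, their fold ratio (a over b)
    and a two-sided Wilcoxon rank-sum p-value.
    """
    def _retained(R, M, cluster):
        sub_r = np.abs(R.loc[cluster.members].to_numpy())
        sub_m = M.values.loc[cluster.members].to_numpy().astype(bool)
        return sub_r[sub_m]

    vals_a = _retained(R_a, M_a, cluster_a)
    vals_b = _retained(R_b, M_b, cluster_b)
    if len(vals_a) == 0 or len(vals_b) == 0:
        raise ValueError("no incidence-retained pairs in one of the groups")
    med_a = float(np.median(vals_a))
    med_b = float(np.median(vals_b))
    p = float(stats.mannwhitneyu(vals_a, vals_b, alternative="two-sided").pvalue)
    return {
        "median_abs_r_a": med_a,
        "median_abs_r_b": med_b,
        "fold_ratio": med_a / med_b,
        "wilcoxon_p": p,
        "n_a": int(len(vals_a)),
        "n_b": int(len(vals_b)),
    }
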