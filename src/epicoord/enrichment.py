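"""NMF cross-validation of hypergraph clusters and gene-set over-representation.

Non-negative matrix factorization of the |r| matrix between DMPs and the
top-ranked background CpGs provides an independent clustering of DMPs to
compare against the hypergraph's central cluster.  The factorization uses
multiplicative updates from a seeded random start and records the
Frobenius objective at every iteration (the update rule guarantees it is
non-increasing).

Gene-set over-representation is a one-sided hypergeometric upper-tail
test per set with BH correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

_EPS = 1e-12


@dataclass
class NMFClustering:
    assignment: pd.Series  # DMP id -> cluster label (0..rank-1)
    W: np.ndarray
    H: np.ndarray
    objective_history: np.ndarray
    n_iter: int


def nmf_cluster_dmps(
    R: pd.DataFrame,
    rank: int = 2,
    max_cols: int = 100_000,
    p_for_ranking=None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFClustering:
    """Cluster DMPs by NMF of |r| against the top-ranked background CpGs.

    ``p_for_ranking`` (aligned with R's columns) ranks CpGs; only the
    ``max_cols`` smallest p-values are kept, mirroring the practice of
    restricting to the most informative CpGs for tractability.  Each DMP is
    assigned to its maximal basis component.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > R.shape[0]:
        raise ValueError("rank exceeds the number of DMPs")
    if p_for_ranking is not None:
        p = np.asarray(p_for_ranking, dtype=float)
        if len(p) != R.shape[1]:
            raise ValueError("p_for_ranking must align with R's columns")
        keep = np.argsort(p, kind="stable")[:max_cols]
        R = R.iloc[:, np.sort(keep)]
    elif R.shape[1] > max_cols:
        R = R.iloc[:, :max_cols]

    V = np.abs(R.to_numpy(dtype=float))
    n, m = V.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank) if V.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(n, rank)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(rank, m)) * scale + _EPS

    history = []
    prev = None
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        obj = float(np.linalg.norm(V - W @ H, "fro") ** 2)
        history.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, 1.0):
            break
        prev = obj

    assignment = pd.Series(np.argmax(W, axis=1), index=R.index, name="cluster")
    return NMFClustering(
        assignment=assignment,
        W=W,
        H=H,
        objective_history=np.array(history),
        n_iter=len(history),
    )


def cluster_overlap(hypergraph_cluster, nmf: NMFClustering) -> dict:
    """Best-matching Jaccard between a DMP set and the NMF clusters."""
    target = set(hypergraph_cluster)
    best = {"cluster": None, "jaccard": 0.0, "shared": 0, "unique_target": len(target),
            "unique_nmf": 0}
    for lab in sorted(nmf.assignment.unique()):
        members = set(nmf.assignment.index[nmf.assignment == lab])
        shared = target & members
        union = target | members
        j = len(shared) / len(union) if union else 0.0
        if j >= best["jaccard"]:
            best = {
                "cluster": int(lab),
                "jaccard": j,
                "shared": len(shared),
                "unique_target": len(target - members),
                "unique_nmf": len(members - target),
            }
    return best


def hypergeometric_enrichment(query_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets in a query.

    P(X >= overlap) with population ``universe``, ``set_size`` successes
    and ``query_size`` draws; BH-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        overlap = len(query & members)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query))
        )
        rows.append(
            {
                "set_id": set_id,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    return df
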