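"""Global silencing of indirect network associations.

Separates direct from indirect association in a correlation-like matrix G
(unit self-association on the diagonal) via the Barzel-Barabasi closed
form::

    S = (G - I + D((G - I) . G)) . G^-1

where I is the identity and D(X) zeroes the off-diagonal of X.  S scores
direct associations: contributions that flow through intermediate nodes
are suppressed (a correlation chain A-B-C leaves S(A,C) near zero).  The
off-diagonal S values are then standardized to Z-scores and thresholded
into a direct-edge set, and DMP pairs are labelled cis (< 1 Mb apart on
one chromosome) or trans.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SilencedNetwork

logger = logging.getLogger(__name__)


def silence_network(G: np.ndarray, cond_max: float = 1e12) -> np.ndarray:
    """Silenced (direct-association) score matrix for a symmetric G with unit diagonal.

    Uses a pseudo-inverse (and logs the event) when G is near-singular.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    if not np.allclose(np.diag(G), 1.0, atol=1e-8):
        raise ValueError("G must have a unit diagonal")
    n = G.shape[0]
    eye = np.eye(n)
    Gm = G - eye
    D = np.diag(np.diag(Gm @ G))
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > cond_max:
        logger.warning("G is near-singular (cond=%.3g); using pseudo-inverse", cond)
        G_inv = np.linalg.pinv(G)
    else:
        G_inv = np.linalg.inv(G)
    return (Gm + D) @ G_inv


def correlation_association_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation among rows, with an exact unit diagonal."""
    from .hypergraph import row_correlation

    G = row_correlation(values, values)
    np.fill_diagonal(G, 1.0)
    return (G + G.T) / 2.0


def direct_edge_zscores(
    S: np.ndarray, node_ids, z_threshold: float = 2.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Standardize off-diagonal silenced scores and threshold direct edges.

    S is symmetrized first (associations are undirected); Z subtracts the
    mean of the off-diagonal entries and divides by their sample SD.  The
    edge set contains unordered pairs with ``|Z| > z_threshold``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    Ssym = (S + S.T) / 2.0
    off_mask = ~np.eye(n, dtype=bool)
    off = Ssym[off_mask]
    sd = off.std(ddof=1)
    if sd <= 1e-12 * max(1.0, np.abs(off).max()):
        raise ValueError("off-diagonal silenced scores are constant; cannot Z-score")
    Z = np.zeros_like(Ssym)
    Z[off_mask] = (off - off.mean()) / sd
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(Z[iu, ju]) > z_threshold
    edges = pd.DataFrame(
        {
            "probe_i": [node_ids[i] for i in iu[keep]],
            "probe_j": [node_ids[j] for j in ju[keep]],
            "z": Z[iu[keep], ju[keep]],
        }
    )
    return Z, edges


def classify_cis_trans(
    edges: pd.DataFrame, annotation: pd.DataFrame, window: int = 1_000_000
) -> pd.DataFrame:
    """Label edges cis (same chromosome, strictly < ``window`` bp apart) or trans.

    Edges with an endpoint missing from the annotation are labelled
    ``unknown`` and counted in a warning.
    """
    labels = []
    n_unknown = 0
    for _, row in edges.iterrows():
        pi, pj = row["probe_i"], row["probe_j"]
        if pi not in annotation.index or pj not in annotation.index:
            labels.append("unknown")
            n_unknown += 1
            continue
        ci, cj = annotation.loc[pi, "chromosome"], annotation.loc[pj, "chromosome"]
        if ci != cj:
            labels.append("trans")
        else:
            dist = abs(int(annotation.loc[pi, "position"]) -
                       int(annotation.loc[pj, "position"]))
            labels.append("cis" if dist < window else "trans")
    if n_unknown:
        logger.warning("%d edges lack coordinates; labelled unknown", n_unknown)
    out = edges.copy()
    out["label"] = labels
    return out


def build_silenced_network(
    dataset, cluster_members, z_threshold: float = 2.0, window: int = 1_000_000
) -> SilencedNetwork:
    """Silence the per-group central-cluster correlation matrix end to end."""
    values = dataset.values.loc[list(cluster_members)].to_numpy(dtype=float)
    G = correlation_association_matrix(values)
    S = silence_network(G)
    Z, edges = direct_edge_zscores(S, list(cluster_members), z_threshold=z_threshold)
    edges = classify_cis_trans(edges, dataset.annotation, window=window)
    return SilencedNetwork(node_ids=list(cluster_members), G=G, S=(S + S.T) / 2.0,
                           Z=Z, edges=edges)


def _edge_key(row) -> tuple:
    return tuple(sorted((row["probe_i"], row["probe_j"])))


def compare_group_edges(edges_case: pd.DataFrame, edges_control: pd.DataFrame) -> dict:
    """Compare direct-edge sets between groups.

    Reports shared/unique unordered pairs, the {group} x {cis, trans}
    contingency table with a two-sided Fisher's exact p, and a two-sided
    Wilcoxon rank-sum p on the |Z| distributions.  A degenerate (all-zero)
    contingency table is reported with p = 1 and a warning.
    """
    keys_case = {_edge_key(r) for _, r in edges_case.iterrows()}
    keys_control = {_edge_key(r) for _, r in edges_control.iterrows()}
    shared = keys_case & keys_control

    def _ct_counts(edges):
        counts = edges["label"].value_counts() if len(edges) else pd.Series(dtype=int)
        return int(counts.get("cis", 0)), int(counts.get("trans", 0))

    cis_a, trans_a = _ct_counts(edges_case)
    cis_b, trans_b = _ct_counts(edges_control)
    table = np.array([[cis_a, trans_a], [cis_b, trans_b]])
    if table.sum() == 0:
        warnings.warn("empty cis/trans contingency table; Fisher p reported as 1")
        fisher_p = 1.0
    else:
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if len(edges_case) and len(edges_control):
        wilcoxon_p = float(
            stats.mannwhitneyu(
                np.abs(edges_case["z"]), np.abs(edges_control["z"]),
                alternative="two-sided",
            ).pvalue
        )
    else:
        wilcoxon_p = float("nan")
    return {
        "shared": len(shared),
        "unique_case": len(keys_case - keys_control),
        "unique_control": len(keys_control - keys_case),
        "contingency": table.tolist(),
        "fisher_p": fisher_p,
        "wilcoxon_p": wilcoxon_p,
    }
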