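"""Entropy-based quantification of hypergraph coordination.

The Shannon entropy of the distribution of hyperedge dimensions (the
off-diagonal adjacency values over pairs of vertices) measures how
uniform the coordination structure is: a highly uniform network has low
entropy, a diverse one high entropy.  Observed values are compared to
hypergraphs built from randomly selected background CpGs, and pathway-level
differences between groups are assessed with a bootstrap (Bayesian
posterior) comparison of entropy distributions at an 89% credible
interval.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import EntropyResult, MethylationDataset, PathwayEntropyComparison
from .hypergraph import row_correlation

logger = logging.getLogger(__name__)


def edge_dimension_distribution(A: pd.DataFrame, members) -> pd.Series:
    """Relative frequencies of off-diagonal adjacency values among ``members``."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least two members to form edges")
    sub = A.loc[members, members].to_numpy()
    dims = sub[np.triu_indices(len(members), k=1)]
    values, counts = np.unique(dims, return_counts=True)
    freq = counts / counts.sum()
    return pd.Series(freq, index=values, name="frequency")


def shannon_entropy(dist) -> float:
    """Shannon entropy in bits of a probability distribution.

    ``dist`` is any sequence of probabilities summing to 1 (zero-mass
    terms contribute nothing).
    """
    p = np.asarray(dist, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution sums to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _hypergraph_entropy(X: np.ndarray, Y: np.ndarray) -> tuple[float, int]:
    """Entropy of off-diagonal edge dimensions for vertices X vs background Y.

    Numpy fast path of the full construction: bipartite correlation ->
    SD-of-|r| binarization -> adjacency -> entropy of off-diagonal values.
    """
    R = np.abs(row_correlation(X, Y))
    t = R.std(ddof=1)
    if t == 0:
        raise ValueError("degenerate correlation structure: SD of |r| is zero")
    M = (R > t).astype(np.int64)
    A = M @ M.T
    dims = A[np.triu_indices(A.shape[0], k=1)]
    _, counts = np.unique(dims, return_counts=True)
    freq = counts / counts.sum()
    return float(-(freq * np.log2(freq)).sum()), len(dims)


def central_cluster_entropy(
    dataset: MethylationDataset, cluster_ids, background_ids
) -> tuple[float, int]:
    """Observed entropy of the central cluster's hyperedge dimensions."""
    X = dataset.values.loc[list(cluster_ids)].to_numpy(dtype=float)
    Y = dataset.values.loc[list(background_ids)].to_numpy(dtype=float)
    return _hypergraph_entropy(X, Y)


def central_cluster_entropy_null(
    dataset: MethylationDataset,
    background_ids,
    observed_entropy: float,
    subset_size: int = 100,
    n_iter: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> EntropyResult:
    """Random-CpG null for the central-cluster entropy.

    Per iteration ``subset_size`` background CpGs are drawn without
    replacement to serve as pseudo-DMPs, the full hypergraph construction
    is re-run against the remaining background, and the entropy of all
    off-diagonal edge dimensions is recorded.  The empirical p-value is
    one-sided toward low entropy (more ordered than random), smoothed:
    ``(1 + #{null <= observed}) / (1 + n_iter)``.
    """
    if subset_size < 3:
        raise ValueError("subset_size must be at least 3")
    background_ids = list(background_ids)
    if len(background_ids) < subset_size + 2:
        raise ValueError("background smaller than subset_size")
    rng = np.random.default_rng(seed)
    pool = dataset.values.loc[background_ids].to_numpy(dtype=float)
    n_bg = len(background_ids)
    null_values = np.empty(n_iter)
    n_edges = subset_size * (subset_size - 1) // 2
    for i in range(n_iter):
        idx = rng.choice(n_bg, size=subset_size, replace=False)
        rest = np.setdiff1d(np.arange(n_bg), idx, assume_unique=False)
        null_values[i], _ = _hypergraph_entropy(pool[idx], pool[rest])
    if two_sided:
        lo = (1 + int((null_values <= observed_entropy).sum())) / (1 + n_iter)
        hi = (1 + int((null_values >= observed_entropy).sum())) / (1 + n_iter)
        p = min(1.0, 2 * min(lo, hi))
    else:
        p = (1 + int((null_values <= observed_entropy).sum())) / (1 + n_iter)
    return EntropyResult(
        entropy=float(observed_entropy),
        n_edges=n_edges,
        null_values=null_values,
        empirical_p=float(p),
    )


def map_genes_to_probes(annotation: pd.DataFrame, genes) -> list:
    """Probes whose annotated gene symbol is in ``genes``."""
    genes = set(genes)
    return list(annotation.index[annotation["gene"].isin(genes)])


def pathway_entropy_bayes(
    dataset_case: MethylationDataset,
    dataset_control: MethylationDataset,
    gene_sets: dict,
    annotation: pd.DataFrame,
    n_graphs: int = 100,
    n_resample: int = 10_000,
    ci: float = 0.89,
    seed: int = 0,
    subset_fraction: float = 0.8,
    background_ids=None,
    min_cpgs: int = 3,
) -> list[PathwayEntropyComparison]:
    """Bayesian comparison of per-pathway hypergraph entropy between groups.

    Per pathway and group, ``n_graphs`` hypergraphs are built from
    subsampled subsets (``subset_fraction`` of the pathway's mapped CpGs,
    without replacement) against the background, and the entropy of each is
    recorded.  Each group's mean entropy is then given a Bayesian posterior
    under a normal model with a noninformative (Jeffreys) prior, whose
    marginal is the scaled Student t ``mean + (s / sqrt(n)) t_{n-1}``;
    ``n_resample`` posterior draws of the difference (case minus control)
    form the posterior difference distribution.  A pathway is significant
    when the equal-tailed ``ci`` credible interval of that difference
    excludes 0.

    Pathways mapping to fewer than ``min_cpgs`` probes are skipped with a
    warning.
    """
    if not 0 < ci < 1:
        raise ValueError("ci must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    results = []
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    for pathway_id in sorted(gene_sets):
        mapped = map_genes_to_probes(annotation, gene_sets[pathway_id])
        mapped = [p for p in mapped if p in dataset_case.probe_ids]
        if len(mapped) < min_cpgs:
            logger.warning(
                "pathway %s maps to %d CpGs (< %d); skipped",
                pathway_id, len(mapped), min_cpgs,
            )
            continue
        size = max(min_cpgs, int(round(subset_fraction * len(mapped))))
        entropies = {}
        for name, ds in (("case", dataset_case), ("control", dataset_control)):
            if background_ids is None:
                bg = ds.probe_ids.difference(mapped)
            else:
                bg = pd.Index(background_ids).difference(mapped)
            pool = ds.values.loc[mapped].to_numpy(dtype=float)
            bg_arr = ds.values.loc[bg].to_numpy(dtype=float)
            vals = np.empty(n_graphs)
            for g in range(n_graphs):
                idx = rng.choice(len(mapped), size=size, replace=False)
                vals[g], _ = _hypergraph_entropy(pool[idx], bg_arr)
            entropies[name] = vals
        def _posterior_mean_draws(vals: np.ndarray) -> np.ndarray:
            n = len(vals)
            se = vals.std(ddof=1) / np.sqrt(n)
            return vals.mean() + se * rng.standard_t(df=n - 1, size=n_resample)

        diff = _posterior_mean_draws(entropies["case"]) - _posterior_mean_draws(
            entropies["control"]
        )
        ci_low, ci_high = np.quantile(diff, [lo_q, hi_q])
        results.append(
            PathwayEntropyComparison(
                pathway_id=pathway_id,
                entropy_case=entropies["case"],
                entropy_control=entropies["control"],
                posterior_difference=diff,
                ci_low=float(ci_low),
                ci_high=float(ci_high),
                significant=not (ci_low <= 0.0 <= ci_high),
            )
        )
    return results
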