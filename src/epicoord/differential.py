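"""Differentially methylated points (DMPs) and regions (DMRs).

DMPs: per-probe two-group ordinary-least-squares fit, equivalent to the
pooled-variance t-test, with Benjamini-Hochberg FDR control at
``alpha = 1e-4``.

DMRs: maximal same-chromosome runs of significant DMPs with inter-probe
gaps <= 300 bp and at least eight members, scored by the sum of member
effects against a group-label permutation null.  The permutation p-value
for a region is the smoothed fraction of permuted regions (pooled over
permutations) whose |statistic| reaches the observed one; the FWER is the
smoothed fraction of permutations whose most extreme region reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationDataset


def _group_ttest(values: np.ndarray, case_mask: np.ndarray):
    """Vectorized pooled-variance two-sample t-test per row.

    Returns (effect, t, p) with effect = mean(case) - mean(control).
    """
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    x1 = values[:, case_mask]
    x2 = values[:, ~case_mask]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    return effect, t, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def test_dmps(
    dataset: MethylationDataset, alpha: float = 1e-4, threshold_on: str = "q"
) -> pd.DataFrame:
    """Per-probe two-group linear-model test with BH FDR.

    Returns a DMP table indexed by probe id with columns ``effect``
    (case - control), ``statistic``, ``p``, ``q``, ``direction`` (hyper if
    effect > 0, else hypo) and ``significant`` (q < alpha).

    ``threshold_on="p"`` applies ``alpha`` to the raw p-value instead; this
    is useful for calibration studies where an FDR cutoff would select no
    probes at all.
    """
    if dataset.scale not in ("M", "zscore"):
        raise ValueError("test_dmps expects M-values or z-scores")
    if threshold_on not in ("q", "p"):
        raise ValueError("threshold_on must be 'q' or 'p'")
    effect, t, p = _group_ttest(dataset.values.to_numpy(dtype=float),
                                dataset.case_mask())
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "effect": effect,
            "statistic": t,
            "p": p,
            "q": q,
            "direction": np.where(effect > 0, "hyper", "hypo"),
            "significant": (q if threshold_on == "q" else p) < alpha,
        },
        index=dataset.probe_ids,
    )


@dataclass
class CandidateRegion:
    chromosome: str
    start: int
    end: int
    probe_ids: list


def _runs(chrom_codes: np.ndarray, pos: np.ndarray, max_gap: int, min_probes: int):
    """Start/end slice bounds of gap-constrained runs over sorted probes.

    ``chrom_codes`` and ``pos`` are the chromosome code and position of the
    significant probes only, sorted by (chromosome, position).  A run
    breaks when the chromosome changes or the gap between consecutive
    significant probes exceeds ``max_gap``.
    """
    n = len(pos)
    if n == 0:
        return []
    breaks = np.flatnonzero(
        (np.diff(chrom_codes) != 0) | (np.diff(pos) > max_gap)
    )
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, n - 1]
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_probes]


def find_candidate_regions(
    dmps: pd.DataFrame,
    annotation: pd.DataFrame,
    max_gap: int = 300,
    min_probes: int = 8,
) -> list[CandidateRegion]:
    """Maximal runs of significant DMPs with gaps <= ``max_gap`` bp.

    Runs shorter than ``min_probes`` are discarded ("more than seven"
    probes is read as >= 8).  Output is sorted by chromosome then start and
    invariant to input row order.
    """
    sig = dmps.index[dmps["significant"]]
    if len(sig) == 0:
        return []
    ann = annotation.loc[sig, ["chromosome", "position"]].sort_values(
        ["chromosome", "position"]
    )
    chrom = ann["chromosome"].to_numpy()
    codes = pd.factorize(chrom)[0]
    pos = ann["position"].to_numpy()
    ids = ann.index.to_numpy()
    return [
        CandidateRegion(
            chromosome=str(chrom[s]),
            start=int(pos[s]),
            end=int(pos[e]),
            probe_ids=list(ids[s : e + 1]),
        )
        for s, e in _runs(codes, pos, max_gap, min_probes)
    ]


def _region_stats(effects: pd.Series, regions: list[CandidateRegion]) -> np.ndarray:
    return np.array(
        [effects.loc[r.probe_ids].sum() for r in regions], dtype=float
    )


def permutation_region_test(
    dataset: MethylationDataset,
    regions: list[CandidateRegion],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 1e-4,
    max_gap: int = 300,
    min_probes: int = 8,
    threshold_on: str = "q",
) -> pd.DataFrame:
    """Score candidate regions against a group-label permutation null.

    For every permutation of the sample labels the full DMP -> candidate
    region pipeline is re-run at the same thresholds.  Per observed region:
    ``p = (1 + #{permuted regions with |stat| >= |obs|}) / (1 + total
    permuted regions)`` and ``fwer = (1 + #{permutations whose max |stat|
    >= |obs|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for stable tail estimates")
    if not regions:
        return pd.DataFrame(
            columns=["chromosome", "start", "end", "n_probes", "value", "p", "fwer",
                     "probe_ids"]
        )
    dmps = test_dmps(dataset, alpha=alpha, threshold_on=threshold_on)
    observed = np.abs(_region_stats(dmps["effect"], regions))

    rng = np.random.default_rng(seed)
    values = dataset.values.to_numpy(dtype=float)
    case_mask = dataset.case_mask()
    n_samples = len(case_mask)
    annotation = dataset.annotation

    # probes sorted by genomic coordinate once; per permutation only the
    # significance mask changes
    ann = annotation.loc[dataset.probe_ids, ["chromosome", "position"]]
    order = np.lexsort((ann["position"].to_numpy(),
                        pd.factorize(ann["chromosome"].to_numpy())[0]))
    codes_sorted = pd.factorize(ann["chromosome"].to_numpy())[0][order]
    pos_sorted = ann["position"].to_numpy()[order]

    perm_stats: list[float] = []
    perm_max = np.zeros(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        eff, _, p = _group_ttest(values, case_mask[perm])
        crit = bh_adjust(p) if threshold_on == "q" else p
        sig_sorted = (crit < alpha)[order]
        idx = np.flatnonzero(sig_sorted)
        eff_sig = eff[order][idx]
        for s, e in _runs(codes_sorted[idx], pos_sorted[idx], max_gap, min_probes):
            stat = abs(float(eff_sig[s : e + 1].sum()))
            perm_stats.append(stat)
            if stat > perm_max[b]:
                perm_max[b] = stat

    perm_stats_arr = np.array(perm_stats, dtype=float)
    rows = []
    for r, obs in zip(regions, observed):
        n_ge = int((perm_stats_arr >= obs).sum()) if len(perm_stats_arr) else 0
        p_val = (1 + n_ge) / (1 + len(perm_stats_arr))
        fwer = (1 + int((perm_max >= obs).sum())) / (1 + n_perm)
        rows.append(
            {
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "n_probes": len(r.probe_ids),
                "value": float(dmps.loc[r.probe_ids, "effect"].sum()),
                "p": p_val,
                "fwer": fwer,
                "probe_ids": ";".join(r.probe_ids),
            }
        )
    return pd.DataFrame(rows)
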