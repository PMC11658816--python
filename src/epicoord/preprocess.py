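"""Harmonization, probe filtering, M-transform, covariate adjustment, z-scoring.

Mirrors the standard two-array methylation workflow: intersect probes
across array platforms, drop cross-reactive / sex-chromosome /
age-associated probes, logit-transform beta values to M-values, regress
out known covariates (e.g. estimated cell-type proportions), then z-score
each probe across all samples pooled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import SEX_CHROMOSOMES, MethylationDataset

logger = logging.getLogger(__name__)


def harmonize_probes(datasets: list[MethylationDataset]) -> list[MethylationDataset]:
    """Restrict every dataset to the common probe set, in sorted order."""
    if len(datasets) < 2:
        raise ValueError("harmonize_probes needs at least two datasets")
    common = datasets[0].probe_ids
    for ds in datasets[1:]:
        common = common.intersection(ds.probe_ids)
    if len(common) == 0:
        for i, a in enumerate(datasets):
            for j, b in enumerate(datasets[i + 1:], start=i + 1):
                if len(a.probe_ids.intersection(b.probe_ids)) == 0:
                    raise ValueError(
                        f"datasets {i} and {j} share zero probes; cannot harmonize"
                    )
        raise ValueError("probe intersection across datasets is empty")
    common = common.sort_values()
    return [ds.restrict_probes(common) for ds in datasets]


def filter_probes(
    dataset: MethylationDataset,
    exclude_flags: set[str] = frozenset({"cross_reactive", "age_associated"}),
    exclude_sex: bool = True,
) -> tuple[MethylationDataset, dict]:
    """Drop probes carrying exclusion flags or mapping to sex chromosomes.

    Returns the filtered dataset and a removal report: counts per reason
    (a probe carrying several flags is counted under each reason but
    removed once; ``total_removed`` counts probes).
    """
    ann = dataset.annotation.loc[dataset.probe_ids]
    report = {flag: 0 for flag in sorted(exclude_flags)}
    remove = np.zeros(len(ann), dtype=bool)
    for flag in sorted(exclude_flags):
        hit = np.array([flag in f for f in ann["flags"]])
        report[flag] = int(hit.sum())
        remove |= hit
    if exclude_sex:
        sex = ann["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
        report["sex_chromosome"] = int(sex.sum())
        remove |= sex
    report["total_removed"] = int(remove.sum())
    report["retained"] = int((~remove).sum())
    if report["retained"] == 0:
        raise ValueError("all probes removed by filtering")
    keep = ann.index[~remove]
    logger.info("filter_probes removed %d probes (%s)", report["total_removed"], report)
    return dataset.restrict_probes(keep), report


def beta_to_m(dataset: MethylationDataset, epsilon: float = 1e-6) -> MethylationDataset:
    """Logit-transform beta values to M-values: ``M = log2(b / (1 - b))``.

    Beta values are clipped into ``[epsilon, 1 - epsilon]`` first so the
    transform stays finite at the boundaries.
    """
    if dataset.scale != "beta":
        raise ValueError(f"beta_to_m requires a beta-scale dataset, got {dataset.scale!r}")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = dataset.values.to_numpy()
    if b.min() < 0 or b.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    return MethylationDataset(
        values=pd.DataFrame(m, index=dataset.probe_ids, columns=dataset.sample_ids),
        group=dataset.group,
        annotation=dataset.annotation,
        scale="M",
    )


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Analytic inverse of the M-transform: ``b = 2**M / (1 + 2**M)``."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


def adjust_covariates(
    dataset: MethylationDataset, covariates: pd.DataFrame
) -> MethylationDataset:
    """Replace each probe row by covariate-fit residuals plus the probe mean.

    ``covariates`` is a samples x k matrix (rows aligned with sample ids);
    an intercept column is added internally.  Raises on rank-deficient
    design (including k >= n_samples).
    """
    cov = covariates.reindex(dataset.sample_ids)
    if cov.isna().any().any():
        raise ValueError("covariate rows must align with dataset samples")
    n, k = cov.shape
    if k >= n:
        raise ValueError("need fewer covariates than samples")
    X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    V = dataset.values.to_numpy()
    beta_hat, *_ = np.linalg.lstsq(X, V.T, rcond=None)
    resid = V - (X @ beta_hat).T
    out = resid + V.mean(axis=1, keepdims=True)
    return MethylationDataset(
        values=pd.DataFrame(out, index=dataset.probe_ids, columns=dataset.sample_ids),
        group=dataset.group,
        annotation=dataset.annotation,
        scale=dataset.scale,
    )


def zscore_normalize(dataset: MethylationDataset) -> tuple[MethylationDataset, dict]:
    """Per-probe z-score across all samples pooled (sample SD, n-1 denominator).

    Constant probes have undefined z-scores and are dropped; the report
    gives their count.
    """
    if dataset.n_samples < 2:
        raise ValueError("z-scoring needs at least two samples")
    V = dataset.values.to_numpy(dtype=float)
    sd = V.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all probes are constant; nothing to normalize")
    report = {"constant_dropped": int(constant.sum()), "retained": int((~constant).sum())}
    if constant.any():
        logger.info("zscore_normalize dropped %d constant probes", report["constant_dropped"])
    V = V[~constant]
    sd = sd[~constant]
    z = (V - V.mean(axis=1, keepdims=True)) / sd[:, None]
    return (
        MethylationDataset(
            values=pd.DataFrame(
                z, index=dataset.probe_ids[~constant], columns=dataset.sample_ids
            ),
            group=dataset.group,
            annotation=dataset.annotation,
            scale="zscore",
        ),
        report,
    )
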