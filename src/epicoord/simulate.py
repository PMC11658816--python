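"""Synthetic two-group methylome generator with full ground truth.

The generative model, per sample ``i`` and probe ``j``::

    m_ij = mu_j + delta_j * case_i + sum_k lambda_jk(group_i) * f_ik + eps_ij

with ``eps ~ Normal(0, noise_sd)`` and ``f_ik ~ Normal(0, 1)`` latent factor
scores.  ``delta_j`` is ``+/- dmp_effect`` for planted differentially
methylated probes (DMPs) and 0 elsewhere.  Each latent factor links a block
of coordinated DMPs to a block of background CpGs via loadings whose
magnitude is group specific: these blocks are the planted hyperedges that
the hypergraph stage should recover, and the group-specific loading
strength is the single knob producing entropy and |r| differences between
groups.

Beta values are returned as ``logistic(m * ln 2)`` so that the downstream
M-transform ``log2(b / (1 - b))`` inverts the simulation exactly.

A single integer seed drives a hierarchical stream (annotation, structure,
factors, noise) so that each component is independently reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    EXCLUSION_FLAGS,
    GROUPS,
    ISLAND_RELATIONS,
    SEX_CHROMOSOMES,
    GroundTruth,
    MethylationDataset,
    SimulationConfig,
    validate_annotation,
)

# fixed stream keys so each sub-generator is reproducible on its own
_STREAM_ANNOTATION = 1
_STREAM_STRUCTURE = 2
_STREAM_FACTORS = 3
_STREAM_NOISE = 4
_STREAM_GENESETS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Place probes on chromosomes and realize planted region runs.

    Returns an annotation table indexed by probe id with strictly
    increasing positions per chromosome.  Probes belonging to a planted
    region run are named ``dmr<k>_p<i>`` and sit at exactly the requested
    positions; remaining probes are spread over ``n_chromosomes`` autosomes
    at random spacings.

    Raises
    ------
    ValueError
        If two region specs on one chromosome overlap.
    """
    config.validate()
    _check_dmr_overlap(config.dmr_specs)
    rng = _rng(config.seed, _STREAM_ANNOTATION)

    n_dmr_probes = sum(s.probe_count for s in config.dmr_specs)
    if n_dmr_probes > config.n_probes:
        raise ValueError("dmr_specs require more probes than n_probes")
    n_background = config.n_probes - n_dmr_probes

    chromosomes = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    rows = []
    # background probes round-robin over chromosomes with random spacings
    per_chrom = np.array_split(np.arange(n_background), len(chromosomes))
    for chrom, idx in zip(chromosomes, per_chrom):
        gaps = rng.integers(500, 5000, size=len(idx))
        positions = 10_000 + np.cumsum(gaps)
        for pos in positions:
            rows.append({"chromosome": chrom, "position": int(pos)})
    # planted region runs at exact positions
    for k, spec in enumerate(config.dmr_specs):
        for i in range(spec.probe_count):
            rows.append(
                {
                    "chromosome": spec.chromosome,
                    "position": spec.start + i * spec.spacing,
                    "dmr_run": k,
                }
            )

    ann = pd.DataFrame(rows)
    if "dmr_run" not in ann.columns:
        ann["dmr_run"] = np.nan
    # run positions are authoritative; nudge background probes off any
    # occupied coordinate so positions are strictly increasing per chromosome
    for chrom in ann["chromosome"].unique():
        on_chrom = ann["chromosome"] == chrom
        fixed = set(ann.loc[on_chrom & ann["dmr_run"].notna(), "position"])
        mask = on_chrom & ann["dmr_run"].isna()
        pos = ann.loc[mask, "position"].to_numpy()
        used = set(fixed)
        for j in range(len(pos)):
            while pos[j] in used:
                pos[j] += 1
            used.add(pos[j])
        ann.loc[mask, "position"] = pos
    ann = ann.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)

    # probe ids: region probes keep a recognizable name
    ids = []
    counter = 0
    for _, row in ann.iterrows():
        if not np.isnan(row.get("dmr_run", np.nan)):
            k = int(row["dmr_run"])
            ids.append(f"dmr{k}_p{int(row['position'])}")
        else:
            ids.append(f"cg{counter:06d}")
            counter += 1
    ann.index = pd.Index(ids, name="probe_id")

    ann["island_relation"] = rng.choice(
        ISLAND_RELATIONS, size=len(ann), p=[0.35, 0.2, 0.1, 0.35]
    )
    # gene symbols: consecutive probes share a symbol, a fraction unannotated
    gene_block = np.arange(len(ann)) // config.probes_per_gene
    genes = np.array([f"GENE{b:05d}" for b in gene_block], dtype=object)
    genes[rng.random(len(ann)) < config.unannotated_gene_fraction] = ""
    ann["gene"] = genes

    flags = [set() for _ in range(len(ann))]
    for flag in ("cross_reactive", "age_associated"):
        frac = config.flag_fractions.get(flag, 0.0)
        if frac > 0:
            hit = rng.random(len(ann)) < frac
            for i in np.flatnonzero(hit):
                flags[i].add(flag)
    sex = ann["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
    for i in np.flatnonzero(sex):
        flags[i].add("sex_chromosome")
    ann["flags"] = [frozenset(f) for f in flags]

    ann = ann.drop(columns=["dmr_run"], errors="ignore")
    validate_annotation(ann)
    return ann


def _check_dmr_overlap(specs) -> None:
    by_chrom: dict = {}
    for spec in specs:
        by_chrom.setdefault(spec.chromosome, []).append(spec)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping dmr_specs on {chrom}: "
                    f"[{a.start}, {a.end}] collides with [{b.start}, {b.end}]"
                )


def generate_gene_sets(
    annotation: pd.DataFrame, n_sets: int, set_size: int, seed: int
) -> dict:
    """Draw ``n_sets`` gene sets of ``set_size`` distinct symbols from the annotation.

    Returns a mapping ``set_id -> sorted list of gene symbols`` that
    round-trips through GMT (see :mod:`epicoord.io`).
    """
    genes = sorted(set(annotation["gene"]) - {""})
    if set_size > len(genes):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(genes)} distinct gene symbols"
        )
    rng = _rng(seed, _STREAM_GENESETS)
    sets = {}
    for k in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"SET{k:03d}"] = sorted(members)
    return sets


def simulate_methylome(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationDataset, GroundTruth]:
    """Simulate beta values under the latent-factor model and return ground truth."""
    config.validate()
    validate_annotation(annotation)
    n_probes = len(annotation)
    if config.n_dmps > n_probes:
        raise ValueError("n_dmps exceeds available probes")

    struct_rng = _rng(config.seed, _STREAM_STRUCTURE)
    factor_rng = _rng(config.seed, _STREAM_FACTORS)
    noise_rng = _rng(config.seed, _STREAM_NOISE)

    probe_ids = annotation.index
    dmr_probe_mask = probe_ids.str.startswith("dmr")
    dmr_probe_ids = list(probe_ids[dmr_probe_mask])
    n_single = config.n_dmps - len(dmr_probe_ids)
    if n_single < 0:
        raise ValueError("n_dmps smaller than the number of planted region probes")
    non_dmr = probe_ids[~dmr_probe_mask]
    single_dmps = list(struct_rng.choice(non_dmr, size=n_single, replace=False))
    dmp_ids = set(dmr_probe_ids) | set(single_dmps)

    # coordinated block: singleton DMPs tied to latent factors
    if config.n_coordinated_dmps > len(single_dmps):
        raise ValueError("n_coordinated_dmps exceeds available non-region DMPs")
    coordinated = list(struct_rng.choice(single_dmps, size=config.n_coordinated_dmps,
                                         replace=False))
    background_pool = [p for p in probe_ids if p not in dmp_ids]
    if config.n_hyperedge_cpgs > len(background_pool):
        raise ValueError("n_hyperedge_cpgs exceeds available background probes")
    hyperedge_cpgs = list(struct_rng.choice(background_pool,
                                            size=config.n_hyperedge_cpgs,
                                            replace=False))

    # per-probe baseline and group effect
    mu = struct_rng.normal(0.0, 1.0, size=n_probes)
    delta = np.zeros(n_probes)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    # one consistent sign per planted region (hyper- or hypomethylated run)
    run_labels = sorted({p.split("_")[0] for p in dmr_probe_ids})
    for run in run_labels:
        sign = 1.0 if struct_rng.random() < 0.5 else -1.0
        for p in dmr_probe_ids:
            if p.startswith(run + "_"):
                delta[probe_pos[p]] = sign * config.dmp_effect
    for p in single_dmps:
        sign = 1.0 if struct_rng.random() < 0.5 else -1.0
        delta[probe_pos[p]] = sign * config.dmp_effect

    # factor loadings: sign per probe, magnitude per group
    loading_sign = np.zeros((n_probes, config.n_factors))
    dmp_blocks = np.array_split(np.array(coordinated), config.n_factors)
    cpg_blocks = np.array_split(np.array(hyperedge_cpgs), config.n_factors)
    for k, (dblk, cblk) in enumerate(zip(dmp_blocks, cpg_blocks)):
        for p in np.concatenate([dblk, cblk]):
            loading_sign[probe_pos[p], k] = 1.0 if struct_rng.random() < 0.5 else -1.0

    sample_ids = [f"case_{i:03d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:03d}" for i in range(config.n_controls)
    ]
    group = pd.Series(
        ["case"] * config.n_cases + ["control"] * config.n_controls,
        index=sample_ids,
        name="group",
    )
    n_samples = len(sample_ids)
    is_case = (group == "case").to_numpy().astype(float)

    scores = factor_rng.normal(0.0, 1.0, size=(n_samples, config.n_factors))
    strength = np.array(
        [config.loading_strength_by_group[g] for g in group], dtype=float
    )
    # m = mu + delta*case + (sign * strength_by_sample) @ f + noise
    m = (
        mu[:, None]
        + np.outer(delta, is_case)
        + loading_sign @ (scores.T * strength[None, :])
        + noise_rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    )
    beta = expit(m * np.log(2.0))

    values = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    dataset = MethylationDataset(values=values, group=group,
                                 annotation=annotation, scale="beta")

    loadings = {
        g: pd.DataFrame(
            loading_sign * config.loading_strength_by_group[g],
            index=probe_ids,
            columns=[f"factor{k}" for k in range(config.n_factors)],
        )
        for g in GROUPS
    }
    dmr_intervals = []
    for run in run_labels:
        members = [p for p in dmr_probe_ids if p.startswith(run + "_")]
        pos = annotation.loc[members, "position"]
        dmr_intervals.append(
            (annotation.loc[members[0], "chromosome"], int(pos.min()), int(pos.max()))
        )
    truth = GroundTruth(
        dmp_ids=dmp_ids,
        dmr_intervals=dmr_intervals,
        factor_loadings=loadings,
        coordinated_cluster_ids=set(coordinated),
        hyperedge_cpg_ids=set(hyperedge_cpgs),
    )
    return dataset, truth
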