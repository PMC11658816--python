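"""End-to-end orchestration: simulate -> preprocess -> DMP/DMR -> hypergraphs
-> entropy -> silencing -> validation, with a run manifest.

Every run writes a ``manifest.json`` echoing the fully resolved
configuration (every threshold actually applied) plus per-stage record
counts, so a run is auditable and reruns with the same seed are
reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coordination, differential, enrichment, hypergraph, io, preprocess, silencing
from .datatypes import DMRSpec, SimulationConfig
from .simulate import generate_gene_sets, generate_probe_annotation, simulate_methylome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved thresholds and toggles for a full analysis run."""

    seed: int = 0
    out_dir: str = "epicoord_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # stage toggles
    run_dmr: bool = True
    run_entropy: bool = True
    run_silencing: bool = True
    run_validation: bool = True
    # thresholds (documented defaults)
    alpha: float = 1e-4          # DMP FDR cutoff
    max_gap: int = 300           # bp between DMPs within one region
    min_probes: int = 8          # "more than seven" DMPs per region
    n_perm: int = 200            # label permutations for region scoring
    fraction: float = 0.95       # peripheral CpG association fraction
    min_cluster_size: int = 10
    subset_size: int = 100       # random-CpG null pseudo-DMP count
    n_iter: int = 200            # random-CpG null iterations
    n_graphs: int = 100          # pathway hypergraph iterations
    n_resample: int = 10_000     # posterior bootstrap resamples
    ci: float = 0.89             # credible interval for pathway entropy
    window: int = 1_000_000      # cis/trans distance cutoff, bp
    z_threshold: float = 2.0     # direct-edge |Z| cutoff
    nmf_rank: int = 2
    n_gene_sets: int = 10
    gene_set_size: int = 20
    background_cap: int | None = None  # cap background CpGs for entropy nulls

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if not 0 < self.ci < 1:
            raise ValueError("ci must lie in (0, 1)")
        if self.min_probes < 2 or self.max_gap < 1 or self.window < 1:
            raise ValueError("region/window thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        dmr_specs = sim_raw.pop("dmr_specs", None)
        sim = SimulationConfig(**sim_raw)
        if dmr_specs is not None:
            sim.dmr_specs = [DMRSpec(**s) for s in dmr_specs]
        return cls(simulation=sim, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    manifest: dict = {"config": config.to_jsonable(), "stages": {}}

    def _finish(stage: str, **stats):
        manifest["stages"][stage] = stats
        logger.info("stage %s done: %s", stage, stats)
        io.write_json(manifest, out / "manifest.json")

    try:
        # --- simulate -----------------------------------------------------
        sim = config.simulation
        annotation = generate_probe_annotation(sim)
        dataset, truth = simulate_methylome(annotation, sim)
        gene_sets = generate_gene_sets(
            annotation, config.n_gene_sets, config.gene_set_size, seed=config.seed
        )
        io.write_annotation(annotation, out / "annotation.tsv")
        io.write_matrix(dataset.values, out / "beta_matrix.tsv")
        io.write_sample_sheet(dataset.group, out / "samples.csv")
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        io.write_ground_truth(truth, out / "ground_truth.json")
        _finish("simulate", n_probes=len(annotation), n_samples=dataset.n_samples,
                n_planted_dmps=len(truth.dmp_ids))

        # --- preprocess ---------------------------------------------------
        filtered, removal = preprocess.filter_probes(dataset)
        mvals = preprocess.beta_to_m(filtered)
        zdata, zreport = preprocess.zscore_normalize(mvals)
        io.write_json({"removal": removal, "zscore": zreport},
                      out / "preprocess_report.json")
        _finish("preprocess", filtered_out=removal["total_removed"],
                constant_dropped=zreport["constant_dropped"],
                retained=zreport["retained"])

        # --- DMPs ---------------------------------------------------------
        dmps = differential.test_dmps(zdata, alpha=config.alpha)
        dmps.to_csv(out / "dmp_table.tsv", sep="\t")
        sig_ids = set(dmps.index[dmps["significant"]])
        _finish("dmp", n_significant=len(sig_ids))

        # --- DMRs ---------------------------------------------------------
        if config.run_dmr:
            regions = differential.find_candidate_regions(
                dmps, zdata.annotation, max_gap=config.max_gap,
                min_probes=config.min_probes,
            )
            dmr_table = differential.permutation_region_test(
                zdata, regions, n_perm=config.n_perm, seed=config.seed,
                alpha=config.alpha, max_gap=config.max_gap,
                min_probes=config.min_probes,
            )
            dmr_table.to_csv(out / "dmr_table.tsv", sep="\t", index=False)
            _finish("dmr", n_candidates=len(regions),
                    n_fwer05=int((dmr_table["fwer"] < 0.05).sum())
                    if len(dmr_table) else 0)

        # --- per-group hypergraphs (same DMP list, different samples) -----
        dmp_list = sorted(sig_ids) if sig_ids else sorted(truth.dmp_ids)
        graphs = {}
        for grp in ("case", "control"):
            ds_g = zdata.restrict_group(grp)
            R = hypergraph.bipartite_correlation(ds_g, dmp_list)
            M = hypergraph.binarize_incidence(R)
            A = hypergraph.adjacency_from_incidence(M)
            cluster = hypergraph.extract_central_cluster(
                A, min_size=config.min_cluster_size
            )
            peripheral = hypergraph.refine_peripheral_cpgs(
                M, cluster, fraction=config.fraction
            )
            graphs[grp] = {"ds": ds_g, "R": R, "M": M, "A": A,
                           "cluster": cluster, "peripheral": peripheral}
            io.write_sparse_incidence(M, out / f"incidence_{grp}.tsv")
            pd.Series(cluster.members).to_csv(
                out / f"central_cluster_{grp}.tsv", index=False, header=["probe_id"]
            )
            pd.Series(peripheral).to_csv(
                out / f"peripheral_cpgs_{grp}.tsv", index=False, header=["cpg_id"]
            )
        overlap = hypergraph.compare_clusters(
            graphs["case"]["cluster"].members, graphs["control"]["cluster"].members
        )
        strength = hypergraph.peripheral_strength_comparison(
            graphs["case"]["R"], graphs["case"]["M"], graphs["case"]["cluster"],
            graphs["control"]["R"], graphs["control"]["M"], graphs["control"]["cluster"],
        )
        io.write_json({"cluster_overlap": overlap, "peripheral_strength": strength},
                      out / "hypergraph_summary.json")
        _finish("hypergraph",
                cluster_case=len(graphs["case"]["cluster"].members),
                cluster_control=len(graphs["control"]["cluster"].members),
                shared=overlap["shared"],
                peripheral_case=len(graphs["case"]["peripheral"]),
                peripheral_control=len(graphs["control"]["peripheral"]),
                abs_r_fold_ratio=strength["fold_ratio"])

        # --- entropy ------------------------------------------------------
        if config.run_entropy:
            entropy_out = {}
            for grp in ("case", "control"):
                g = graphs[grp]
                background = g["R"].columns
                if config.background_cap and len(background) > config.background_cap:
                    background = background[: config.background_cap]
                obs, n_edges = coordination.central_cluster_entropy(
                    g["ds"], g["cluster"].members, background
                )
                null = coordination.central_cluster_entropy_null(
                    g["ds"], list(background),
                    observed_entropy=obs,
                    subset_size=min(config.subset_size, len(g["cluster"].members)),
                    n_iter=config.n_iter,
                    seed=config.seed,
                )
                entropy_out[grp] = {
                    "entropy": null.entropy,
                    "n_edges": n_edges,
                    "null_mean": float(np.mean(null.null_values)),
                    "empirical_p": null.empirical_p,
                }
            io.write_json(entropy_out, out / "entropy.json")
            _finish("entropy",
                    entropy_case=entropy_out["case"]["entropy"],
                    entropy_control=entropy_out["control"]["entropy"])

        # --- silencing ----------------------------------------------------
        if config.run_silencing:
            nets = {}
            for grp in ("case", "control"):
                g = graphs[grp]
                nets[grp] = silencing.build_silenced_network(
                    g["ds"], g["cluster"].members,
                    z_threshold=config.z_threshold, window=config.window,
                )
                nets[grp].edges.to_csv(out / f"direct_edges_{grp}.tsv",
                                       sep="\t", index=False)
            comparison = silencing.compare_group_edges(
                nets["case"].edges, nets["control"].edges
            )
            io.write_json(comparison, out / "edge_comparison.json")
            _finish("silencing",
                    edges_case=len(nets["case"].edges),
                    edges_control=len(nets["control"].edges),
                    shared=comparison["shared"])

        # --- validation (NMF + enrichment) --------------------------------
        if config.run_validation:
            R_case = graphs["case"]["R"]
            p_rank = np.abs(R_case.to_numpy()).max(axis=0)
            nmf = enrichment.nmf_cluster_dmps(
                R_case, rank=config.nmf_rank,
                p_for_ranking=1.0 - p_rank, seed=config.seed,
            )
            nmf_overlap = enrichment.cluster_overlap(
                graphs["case"]["cluster"].members, nmf
            )
            query_genes = set(
                zdata.annotation.loc[graphs["case"]["cluster"].members, "gene"]
            ) - {""}
            universe = set(zdata.annotation.loc[zdata.probe_ids, "gene"]) - {""}
            enr = enrichment.hypergeometric_enrichment(query_genes, gene_sets, universe)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            io.write_json({"nmf_overlap": nmf_overlap}, out / "nmf_overlap.json")
            _finish("validation", nmf_jaccard=nmf_overlap["jaccard"],
                    n_enriched_q05=int((enr["q"] < 0.05).sum()) if len(enr) else 0)
    except Exception:
        io.write_json(manifest, out / "manifest.json")
        logger.exception("pipeline halted; partial outputs retained in %s", out)
        raise

    io.write_json(manifest, out / "manifest.json")
    return manifest
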