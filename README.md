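# epicoord

Higher-order coordination analysis of two-group DNA methylation data.

Standard differential methylation analysis treats every CpG probe
independently, and region (DMR) analysis only rescues probes that happen to
sit in dense genomic runs. Both ignore how the methylation of a
differentially methylated probe (DMP) is *coordinated* with the rest of the
methylome. `epicoord` models that coordination with hypergraphs: DMPs are
vertices, and every background CpG whose methylation is strongly correlated
with a set of DMPs defines a hyperedge joining them. This exposes
higher-order interactions — including trans-chromosomal ones — that
pairwise networks and DMR calling miss, and it lets case and control
methylomes be modelled separately and compared as network structures.

The package is aimed at epigenomics researchers working with two-group
methylation array data (beta values from 450K/EPIC-style platforms) and at
methodologists who want a fully testable, simulation-backed implementation
of the hypergraph coordination workflow.

## The model

Given a probes × samples matrix, per group:

1. **DMPs** — per-probe two-group OLS fit (pooled-variance t-test) on
   M-values (`M = log2(β/(1−β))`), Benjamini–Hochberg FDR, `q < 1e-4`.
2. **DMRs** — runs of ≥8 significant DMPs with inter-probe gaps ≤300 bp,
   scored by the sum of member effects against a group-label permutation
   null (region p and family-wise error rate over permutation maxima).
3. **Hypergraph** — Pearson correlations `R` between DMPs and all other
   CpGs within one group's samples; binarized at a cutoff equal to the
   standard deviation of `|r|`, giving the incidence matrix `M`; the
   adjacency `A = M·Mᵗ` counts shared correlations (hyperedge dimension)
   per DMP pair. Hierarchical clustering of `A` refines a central cluster
   of highly coordinated DMPs; CpGs associated with >95% of the cluster are
   its peripheral (indirectly co-regulated) CpGs.
4. **Entropy** — Shannon entropy `H = −Σ p·log2 p` of the distribution of
   hyperedge dimensions inside the central cluster, compared with
   hypergraphs of randomly drawn CpGs, and compared between groups per
   pathway via a Bayesian posterior on mean entropy (89% credible
   interval).
5. **Silencing** — the direct-association transform
   `S = (G − I + D((G − I)·G))·G⁻¹` suppresses correlation contributions
   flowing through intermediate nodes; off-diagonal `S` is Z-scored,
   thresholded into a direct-edge set, and edges are labelled cis
   (<1 Mb, same chromosome) or trans.

A synthetic-methylome generator plants all of this structure (DMPs, DMR
runs, a latent-factor coordination block with group-specific strength) with
full ground truth, so every stage is tested against known answers.

## Worked example

```python
import epicoord as ec
from epicoord.datatypes import SimulationConfig

cfg = SimulationConfig(seed=1)              # 22 cases vs 138 controls
ann = ec.generate_probe_annotation(cfg)
dataset, truth = ec.simulate_methylome(ann, cfg)

z, _ = ec.zscore_normalize(ec.beta_to_m(ec.filter_probes(dataset)[0]))
dmps = ec.test_dmps(z, alpha=1e-4)
print(int(dmps["significant"].sum()))       # 180

dmp_list = sorted(dmps.index[dmps["significant"]])
R = ec.bipartite_correlation(z, dmp_list, group="control")
M = ec.binarize_incidence(R)
A = ec.adjacency_from_incidence(M)
cluster = ec.extract_central_cluster(A, min_size=10)
peripheral = ec.refine_peripheral_cpgs(M, cluster)
print(len(cluster.members), len(peripheral))  # 85 494
```

The run recovers 180 of the 192 planted DMPs that survive probe filtering,
with no false discoveries. The 85-member central cluster is exactly the
detected part of the planted coordination block, and the 494 peripheral
CpGs recover the planted hyperedge CpGs with sensitivity 1.00 and
precision 0.98 on this seed.

The same pipeline runs end to end from the shell:

```bash
epicoord run --seed 1 --out run1/       # writes all stage outputs + manifest.json
epicoord simulate --seed 1 --out sim1/  # just the synthetic dataset
```

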