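# Methods

## Scope and design

`epicoord` implements a two-group methylome coordination analysis as a
chain of small, individually testable operations: preprocessing →
differential methylation → per-group hypergraph construction → entropy
quantification → network silencing → independent validation (NMF,
over-representation). A synthetic-data module generates methylomes with
planted structure and full ground truth; all statistical guarantees of the
pipeline are demonstrated on that generator rather than on any particular
public dataset.

## Synthetic methylome generator

Per sample *i* and probe *j* the latent M-value is

    m_ij = mu_j + delta_j * case_i + sum_k lambda_jk(group_i) * f_ik + eps_ij

with `mu_j ~ N(0,1)` probe baselines, `eps ~ N(0, noise_sd)` and factor
scores `f_ik ~ N(0,1)`. `delta_j = ±dmp_effect` for planted DMPs (one
consistent sign per planted region run) and 0 otherwise. Each latent
factor ties a block of coordinated DMPs to a block of background CpGs
through loadings whose sign is per-probe and whose magnitude is
group-specific — the planted hyperedges. Beta values are emitted as
`logistic(m·ln 2)`, so the standard M-transform `log2(b/(1−b))` inverts the
simulation exactly and no transform ambiguity enters the tests.

Defaults encode the emulated study conditions: 2,000 probes over six
autosomes, 22 cases vs 138 controls, 200 planted DMPs (including two
8-probe region runs at 250/200 bp spacing), `dmp_effect = 2` M-units,
`noise_sd = 1`, one latent factor linking 100 coordinated DMPs to 500
background CpGs, loading magnitude 1.5 (case) vs 1.0 (control), 2% of
probes flagged cross-reactive and 2% age-associated. One integer seed
drives a hierarchical stream (annotation / structure / factors / noise), so
each component is reproducible in isolation.

What the generator does *not* emulate: array chemistry (type I/II probe
designs, dye bias), detection-p artifacts, cell-composition heterogeneity
(covariate adjustment is exercised on explicit design matrices instead),
spatial autocorrelation of methylation outside the planted runs, and
non-Gaussian beta-value distributions. Passing tests therefore demonstrate
correctness and calibration of the algorithms under a clean latent-factor
model, not robustness to every artifact of real array data.

## Preprocessing

Probe harmonization intersects probe sets across datasets (sorted order);
filtering removes flagged probes (cross-reactive, age-associated) and sex
chromosomes with a per-reason report; beta values are clipped to
`[1e-6, 1 − 1e-6]` before the logit — far enough out not to move interior
points, close enough in to keep M-values finite. Covariate adjustment
replaces each probe row by OLS residuals plus the probe mean (rank-deficient
designs are rejected). Z-scoring is per probe across all samples pooled
(sample SD, n−1), applied once before any group-wise analysis; constant
probes are dropped and counted. Adjustment precedes z-scoring; the order is
configurable by composing the functions the other way.

## Differential methylation

DMPs: per-probe pooled-variance two-sample t statistic (equivalent to the
two-group OLS fit), BH step-up FDR, default `q < 1e-4`. The effect is the
case-minus-control mean difference; `hyper` means the effect is positive.
For calibration studies `test_dmps(..., threshold_on="p")` thresholds the
raw p-value instead, because under a global null an FDR cutoff selects no
probes and the region machinery would have nothing to score.

DMRs: maximal runs of significant DMPs on one chromosome with inter-probe
gaps ≤ 300 bp and ≥ 8 members ("more than seven"). The region statistic is
the sum of member effects — it grows with both run length and magnitude.
Significance comes from group-label permutations that re-run the complete
DMP → region pipeline at identical thresholds: the region p-value is the
smoothed fraction `(1+k)/(1+N)` of all permuted regions whose |statistic|
reaches the observed one, and the FWER the smoothed fraction of
permutations whose most extreme region does. Labels (not positions) are
permuted so the probe correlation structure is preserved under the null.
`n_perm ≥ 100` is enforced; the `+1` smoothing avoids zero p-values at
finite permutation counts.

## Hypergraph construction

Correlations are Pearson, computed on z-scored M-values within one group's
samples between the DMP list and every other retained CpG (the background
can be capped for tractability; constant rows correlate 0 and are counted).
The binarization cutoff is the sample SD (n−1) of all |r| entries pooled —
a data-driven threshold that rises when strong coordination inflates the
|r| distribution. Incidence `M` (DMPs × CpGs, binary) gives adjacency
`A = M·Mᵗ`; the off-diagonal entry of a DMP pair is its hyperedge
dimension.

Central cluster: average-linkage hierarchical clustering (Euclidean
distance between adjacency rows), scanning cuts k = 2…20 and stopping at
the smallest k whose highest-scoring cluster (mean internal off-diagonal
dimension) has at least `min_size` members. The rule is deterministic and
seed-free. A perfectly uniform off-diagonal has nothing to refine and
returns the full vertex set. Peripheral CpGs are incidence columns
associated with strictly more than 95% of cluster members (a CpG hitting
exactly 95% is excluded).

## Entropy

Edge dimensions are integers, so entropy is computed on the empirical
distribution over distinct observed dimensions without binning:
`H = −Σ p·log2 p` (bits). The random-CpG null redraws `subset_size`
background CpGs as pseudo-vertices, reruns the full construction, and
records the entropy of all off-diagonal dimensions; the empirical p-value
is one-sided toward low entropy (the direction meaning "more ordered than
random"), smoothed as `(1+k)/(1+n_iter)`.

Pathway comparison: a pathway's CpGs are the probes annotated to its gene
symbols. Per group, `n_graphs = 100` hypergraphs are built from random 80%
subsets of the mapped CpGs (without replacement — a hypergraph needs
distinct vertices, so an m-out-of-n subsample stands in for a bootstrap)
and their entropies recorded. Each group's mean entropy receives a
normal-model Jeffreys posterior, whose marginal is the scaled Student t
`x̄ + (s/√n)·t_{n−1}`; `n_resample = 10,000` posterior draws of the
case-minus-control difference form the posterior difference distribution,
and the pathway is significant when the equal-tailed 89% credible interval
(quantiles 0.055 and 0.945) excludes zero. Measured on independent null
datasets (identical groups), the flag rate is ≈ 9% at the 89% interval —
close to the nominal 11% — while pathways with 1.5× group-specific
loadings are flagged essentially always at these sizes. A naive
percentile-bootstrap of the means was measurably anti-conservative (≈ 15%)
and was not retained.

## Network silencing

The silenced score matrix is `S = (G − I + D((G−I)·G))·G⁻¹` where `D(·)`
zeroes off-diagonal entries. `G` is the per-group Pearson correlation
matrix over central-cluster members with unit diagonal — the silencing
formula assumes unit self-association, which the integer adjacency does not
provide. When `G` is singular or near-singular (e.g. more cluster members
than samples in the group), a pseudo-inverse is used and the condition
number logged; this is deterministic and parameter-free, unlike ridge
damping. `S` is symmetrized (associations are undirected; the closed form
is only exactly symmetric for 2×2), its off-diagonals are standardized to
Z-scores, and pairs with `|Z| > 2` (configurable) form the direct-edge set.
Edges are cis when both endpoints share a chromosome and are strictly less
than 1 Mb apart (exactly 1 Mb is trans); different chromosomes are always
trans; missing coordinates yield `unknown` with a warning. Group edge sets
are compared by exact set arithmetic, a two-sided Fisher exact test on the
group × cis/trans table (an all-zero table reports p = 1 with a warning),
and a rank-sum test on |Z|.

## Validation

NMF clusters DMPs from `|r|` against the top-ranked background columns
(default cap 100,000 — far above the synthetic scale, so effectively no
truncation there). Non-negativity uses `|r|`, preserving the magnitude
semantics the hypergraph consumes, rather than a min-shift. The
factorization is a multiplicative-update loop from a seeded uniform random
start, recording the Frobenius objective every iteration (the update rule
guarantees monotone descent, which the tests assert); convergence at
relative change < 1e-6 or 500 iterations; each DMP joins its maximal basis
component. Rank defaults to 2 (coordinated vs not). Over-representation is
a one-sided hypergeometric upper-tail test per gene set against a supplied
universe with BH correction across sets.

## Choices made where the design was open

- **Entropy-direction experiment (group sizes).** Comparing raw entropies
  between groups of 22 and 138 samples mostly measures correlation-
  estimation noise: at n = 22 the null |r| spread dominates the edge-
  dimension variance. The group-difference experiments therefore use
  matched groups (80 vs 80) so that coordination strength is the only knob
  that differs. Mechanism: stronger case loadings inflate the pooled |r|
  SD, raising the binarization cutoff, pruning noise edges and
  concentrating edge dimensions — hence lower case entropy and a case/
  control |r| fold ratio above 1.
- **Per-group correlations use only that group's samples** (the alternative
  — correlating over all samples — would let the larger group dominate
  both models).
- **Random-CpG entropy null draws from non-DMP background CpGs**, so the
  null asks "is the cluster more ordered than an arbitrary same-sized set
  of CpGs?", uncontaminated by differential signal.
- **Region statistic** is the effect sum; the two DMR thresholds (region
  FDR and FWER) are both exposed in configuration rather than hard-wired to
  one reading.

## Numerical conventions

Sample standard deviations use the n−1 denominator everywhere (z-scores,
|r| binarization cutoff, Z-scoring of silenced scores). Correlations are
clipped to [−1, 1] against rounding. Permutation and entropy-null p-values
are add-one smoothed. Ties in the cluster scan break toward fewer
clusters. All randomness flows from explicit integer seeds;
`SeedSequence([seed, stream])` separates annotation, structure, factor and
noise streams in the generator.

## Problem sizes

The shipped test-suite and acceptance-script runs use 400–2,000 probes,
50–160 samples, 100–200 permutations, 100 pathway hypergraphs and 10,000
posterior draws — sizes at which every calibration and recovery property
is measurable in seconds while exercising the same code paths as
full-scale data. The correlation stage is the only quadratic-cost step;
for full arrays its background set can be capped in configuration, with
the cap recorded in the run manifest.

## Known limitations

- Pearson correlation on z-scored M-values assumes approximately linear
  coordination; Spearman is not currently wired through the pipeline
  surface.
- The silencing transform assumes a correlation-like `G`; for clusters
  larger than the group's sample count the pseudo-inverse solution is a
  minimum-norm choice and edge Z-scores should be read comparatively, not
  absolutely.
- The Jeffreys-posterior pathway comparison treats per-graph entropies as
  exchangeable draws; heavy overlap between 80% subsets of a very small
  pathway makes them mildly dependent, which the measured ≈ 9% null flag
  rate suggests is tolerable at the default sizes.
- Gene mapping is exact symbol equality against the annotation table; no
  distance-based promoter/enhancer assignment.
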