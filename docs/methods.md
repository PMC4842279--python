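# Methods

This note documents the models implemented in `awmnet`, the defaults
and why they were chosen, the numerical details, and what the synthetic
data generator does and does not emulate.

## Synthetic multi-breed data

The generator (`awmnet.simulate`) produces the statistical structure
the analysis assumes, at desk scale.

**Allele frequencies.** Ancestral frequencies are drawn uniformly from
the configured MAF range (default 0.1–0.5) and mirrored to either
allele with probability ½. Breed frequencies follow the
Balding–Nichols model: Beta(p(1−F)/F, (1−p)(1−F)/F) around the
ancestral p, clamped to [0.01, 0.99]. F (FST, default 0.1) is the
single knob for between-breed differentiation; the Weir–Cockerham-style
ratio Var(p_breed)/(p̄(1−p̄)) recovers it empirically. This is the
standard minimal model for population differentiation — no attempt is
made to match any real breed's frequency spectrum.

**Genotypes.** Within breed, dosages are Binomial(2, p) under
Hardy–Weinberg. With `ld_block_size > 1`, the two haplotypes of an
individual are copied from one latent uniform per block and per
haplotype, thresholded against each SNP's frequency and flipped with
mutation probability 0.02 — positive within-block LD without the cost
of coalescent simulation. Realistic LD decay, pedigree structure and
sex chromosomes are deliberately out of scope.

**Gene map.** Genes tile each chromosome as 20-kb bodies separated by
30-kb gaps. SNP placement is deterministic allocation, not sampling:
exact fractions fall inside gene bodies (default 35 %), in the 10-kb
flank (25 %), and in the far intergenic zone (remainder), evenly spaced
within each zone. Gene classes are protein-coding by default with
TF/miRNA/lncRNA assigned at the configured fractions (defaults
0.08/0.02/0.02, roughly the relative abundance of annotated regulator
classes in mammalian genomes).

**Phenotypes.** Causal genes are drawn among genes that contain SNPs; a
configurable fraction (default 0.5) is shared by all breeds, the rest
are breed-specific and disjoint. Each causal gene acts through one
causal SNP *chosen independently per breed* from the SNPs inside its
body — so a gene shared across breeds usually acts through different
SNPs in different breeds, which is the mechanism behind the
genes-shared / SNPs-unshared signature the multi-breed comparison
looks for. Per-trait effects of each causal SNP are multivariate normal
with the configured trait correlation matrix (default: blocks of 4
traits at r = 0.6 within, 0.1 between), so the key trait loads on every
causal gene and other traits load through the correlation. An
infinitesimal term over the non-causal SNPs plus Gaussian noise
completes the phenotype; each component is rescaled empirically so the
causal share of genetic variance (default 0.8) and the per-trait
heritability (default 0.35) are realized exactly in-sample. Phenotypes
are produced already adjusted for systematic environmental effects, so
the analysis models fit an intercept only.

Desk-scale defaults are 3 breeds × 500 individuals, 5,000 SNPs on 5
chromosomes, 300 genes, 8 traits. Everything is driven by a single
seed; identical configs give bit-identical output.

**What passing tests do not show.** The generator has no LD between
blocks, no MAF-differentiated causal variants, no dominance or
epistasis, no missing-data patterns, and trait correlations that are
homogeneous across breeds. Results on this generator validate the
*machinery* (selection rules, estimators, set logic), not the method's
behavior on real livestock data.

## GRM and REML

The genomic relationship matrix uses the Yang et al. estimator:
off-diagonals (1/m) Σ (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)) and the
bias-corrected diagonal 1 + (1/m) Σ (x² − (1+2p)x + 2p²)/(2p(1−p)),
with p estimated from the sample and missing dosages mean-imputed at
computation time only.

This estimator is not guaranteed positive semi-definite at finite m —
small SNP subsets routinely give eigenvalues below −1. REML therefore
does not clamp the spectrum; it works in the eigenbasis and keeps
V = σ²_u D + σ²_e I positive by bounding the variance ratio
λ = σ²_u/σ²_e at 0.999/|d_min| when d_min < 0. Only matrices whose
minimum eigenvalue is far below any plausible sampling noise (below
−10 × the mean diagonal) are rejected as not being relationship
matrices.

REML maximizes the restricted likelihood of y = 1μ + u + e by Brent
search over log λ (tolerance 1e−8, search window e^±12) with σ²_e
profiled out. Standard errors come from a central-difference observed
information matrix in (σ²_u, σ²_e); the SE of h² = σ²_u/(σ²_u+σ²_e)
uses the delta method. A flat profile (e.g. an identity-like GRM, where
the two components are unidentifiable) is detected and flagged rather
than reported as converged.

A practical caveat surfaced by the tests: for very small SNP subsets
(m ≲ 20) the noisy Yang diagonal biases subset-h² estimates downward
(≈ 0.31 recovered for a true 0.45 at m = 10, converging by m ≈ 80–160).
This is a property of the estimator, not of the optimizer; subset
comparisons in the variance-partition stage are therefore made at equal
subset sizes, where the bias cancels.

## MLMA scan

Variance components are estimated once per trait under the null and
reused for every SNP (the GCTA `--mlma` convention; the candidate SNP
stays in the GRM — no LOCO by default). Each SNP's effect is the GLS
estimate â = s̃ᵀV⁻¹ỹ / s̃ᵀV⁻¹s̃ with the intercept projected out of
both phenotype and genotype in the V-metric, computed in the GRM
eigenbasis (one rotation of y and of the genotype matrix, then O(n)
per SNP). SE = (s̃ᵀV⁻¹s̃)^{−1/2}; p-values are two-sided normal
(Wald), matching GCTA. Zero-variance SNPs are emitted as missing with a
reason rather than dropped silently. Per-trait missing phenotypes are
handled pairwise: each trait is analyzed on its own complete-record
subset (subsetting the GRM, not re-estimating it), and traits with
fewer than 50 records are skipped with a warning.

## AWM construction

Key-trait SNPs are selected at p ≤ α (α = 0.01, inclusive — the
threshold itself qualifies). Ap is the mean number of *other* traits
associated at α over the key SNPs, rounded half-up and floored at 1;
the count excludes the key trait, since "other phenotypes" is the
operative notion and including the key trait would make every key SNP
count at least one. The pleiotropy rule admits any SNP with ≥ Ap
non-key associations, whether or not it is key-significant.

SNP→gene mapping uses the gene body ± 10 kb (the annotation has no CDS
substructure, so the body stands in for the coding region). A SNP in
two windows goes to the nearer gene, distance 0 inside a body, ties to
the smaller gene start. One representative SNP per gene: smallest
key-trait p, ties by distance then position — significance-first,
because the key trait anchors the whole matrix. Matrix cells are
z-scored per trait over the retained SNP set (sample SD), and columns
are ordered key trait first for reproducible output.

Clustering of rows and columns uses 1 − Pearson correlation and
average linkage (a config knob; average is the default because single
linkage chains badly on correlation matrices and complete linkage is
too sensitive to single outlier profiles). Merge heights are exported
so dendrograms are reproducible.

## PCIT and network reduction

For every trio (x, y, z) the three first-order partial correlations and
the tolerance ε = ⅓ Σ partial/direct are computed; edge (x, y) is
non-significant if some z gives |r_xy| < |ε·r_xz| and |r_xy| <
|ε·r_yz|. Ratios whose direct correlation is 0 are excluded from the
average; a trio with all three excluded imposes no elimination; a trio
with a non-positive partial-correlation denominator (collinearity,
|r| = 1) is skipped and counted. The implementation vectorizes over the
third node (no Python triple loop) and is checked edge-for-edge against
an exhaustive triple-loop reference in the tests.

Reduction keeps edges with |r| ≥ mean(|r|) + k·SD(|r|), k = 2, where
the statistics are computed over PCIT-significant edges only (those are
the edges the method considers real; including eliminated edges would
let noise set the threshold). Sample (n−1) SD by default, population SD
by flag. The comparison is ≥, and with SD = 0 (all equal weights) every
edge is retained. Topology counts exclude isolated genes; centrality
(degree, closeness, betweenness) uses unweighted shortest-path
definitions, computed per connected component.

**Regulator ranking.** Each TF/miRNA/lncRNA node is scored by degree,
by the number of traits its AWM row is co-associated with (|z| ≥ 2.576,
the two-sided 1 % normal quantile — chosen to mirror the p ≤ 0.01
selection threshold on the z scale), and by its neighbor set. A greedy
maximum-coverage pass then selects a compact regulator subset: repeat-
edly take the regulator covering the most not-yet-covered neighbors
(ties: higher degree, then lexicographically smaller id), stopping at
zero marginal gain. Greedy maximum coverage is the documented surrogate
for connectivity-based "information lossless" regulator exploration;
it is transparent, deterministic, and its 1 − 1/e coverage guarantee is
good enough for a ranking that is meant to prioritize, not prove.

## Variance partitioning

A subset GRM (built by `compute_grm` on the subset) plus REML gives the
fraction of phenotypic variance the subset captures. Significance is
empirical: n random subsets of the same size, sampled without
replacement from the post-QC panel, each fitted identically; the
p-value uses the add-one permutation convention
p = (1 + #{null ≥ observed})/(n + 1), so the smallest attainable p with
200 replicates is 1/201. Desk default is 200 replicates; 10,000 is a
config value for full-scale runs. Subsets below 10 SNPs warn
(estimates unstable, see the small-m bias above) but still compute.

## Across-breed comparison

Gene and representative-SNP intersections are exact set operations at
every order. Overlap percentages use the union of the compared sets as
denominator — "total number of genes" is ambiguous otherwise — and raw
counts are always reported alongside so any alternative convention can
be recomputed. SNPs for the common-gene GRM are all post-QC SNPs within
the common genes ± the AWM window, per breed.

## Problem sizes in tests and the acceptance script

Simulation-based checks use 20 replicates at n = 500–600 with
1,500–2,000 SNPs and 150 genes — sizes chosen so each check isolates
the property under test with adequate power (e.g. the null REML check
uses n = 800, m = 400 because the sampling SD of ĥ² scales like
√(2m)/n). The acceptance script runs the same computations at 5
replicates per scenario, which is sufficient for its reported
fractions, and derives every stream from the single `--seed`.

## Known limitations

- PCIT is O(n³) in gene count; fine to a few thousand AWM rows, not
  meant for whole-transcriptome matrices.
- The subset-h² small-m bias described above means absolute subset
  estimates below ~20 SNPs should be read qualitatively.
- The regulator "co-associated traits" count depends on the z
  threshold; 2.576 is a convention, not an inference.
- The generator's deterministic SNP placement makes gene SNP-content
  uniform; real gene-length and SNP-density heterogeneity would widen
  the spread of AWM row counts.
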