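# Methods

This note documents the models, defaults, and design choices behind
`netkda`, and what the synthetic benchmarks do and do not demonstrate.

## Differential expression

**Filtering.** Genes with CPM ≥ 1 (on raw library sizes) in at least one
sample are retained; the boundary is inclusive. With 24 samples of 8–12 M
reads this keeps essentially all genes with ≥ ~10 counts anywhere.

**TMM normalization.** Per-sample scaling factors are the weighted trimmed
mean of per-gene log₂ ratios (M) against a reference sample, double-trimmed
— 30% of genes on each side by M and 5% by average log abundance (A) —
with precision weights from the binomial asymptotic variance of M, then
rescaled to geometric mean 1. The reference is the sample whose 75th CPM
percentile is closest to the cross-sample mean. These are the method's
published defaults; during development the implementation was verified to
5+ decimals against edgeR's `calcNormFactors` on a spiked fixture, and the
shipped tests compare it to an independent loop-based second
implementation at 1e-6.

**Linear model and moderation.** Expression is log₂ CPM with prior count
0.5 on TMM-effective library sizes. Each gene gets a group-means fit over
the six genotypes; residual variances are shrunk toward a prior by
empirical Bayes, with the prior degrees of freedom d₀ and variance s₀²
obtained by moment-matching of log residual variances through
digamma/trigamma identities (the trigamma inverse is solved by Newton
iteration). Moderated t uses d₀ + d_g degrees of freedom. With
heteroscedastic genes this reproduces limma's `eBayes` output to ~1e-8
(checked against Rscript during development); when the observed variance
spread is sub-chi-squared the prior df is infinite and we use s₀² =
exp(mean log s²) rather than limma's arithmetic-mean fallback — a
deliberate, documented simplification that only affects the d₀ = ∞ branch.
Precision-weighted (voom-style) fitting is not implemented; the untrended
log-CPM variant is the default and only path, which is adequate at the
deep, balanced library sizes simulated here.

**Contrasts and signatures.** The six reported pairwise contrasts
(het vs WT, ko vs WT, APP vs WT, APP;ko vs APP, APP;ko vs WT,
APP;ko vs ko) are fixed defaults; BH adjustment is applied within each
contrast. A signature is up = {FDR ≤ 0.05, log2FC > 0} and down likewise;
the threshold boundary is inclusive.

## Enrichment arithmetic

All overlap statistics are the hypergeometric upper tail P(X ≥ k) — the
one-sided Fisher exact test for over-representation — computed via the log
survival function so extreme tails remain representable, plus fold
enrichment kN/(n₁n₂). The 2×2 test is one-sided by design: every use in
this pipeline is an over-representation question. The universe N is always
explicit and carried in every result row; the default universe is the
filtered (expressed) gene set, intersected with network nodes for network
enrichments. Families for BH adjustment are the explicitly requested pair
list (overlap stage), all candidate nodes (driver ranking), or all
detected modules (module stage).

## Key-driver analysis

Directed networks are consumed as edge lists; the union of cohort networks
merges edge sets and cohort tags and is treated as a general digraph
(cycles permitted — union of DAGs need not be acyclic). Layers below a
seed are shortest-directed-distance sets from a breadth-first traversal;
per-layer enrichment is the default (the cumulative-union variant is a
flag) because a printed first-layer membership reads naturally as a
per-layer set. Driver ranking scores each node's cumulative downstream
neighborhood within max_depth = 4 (four layers) against the signature, BH
across candidates, with deterministic tie-breaks (adjusted p ascending,
fold enrichment descending, neighborhood size descending, then node name).
No neighborhood-size bounds restrict the candidate set by default.

## Co-expression modules

Unsigned weighted adjacency |cor|^β with β = 6, the standard topological
overlap transform, average-linkage clustering on 1 − TOM, and a static cut
at height 0.98 with min module size 30; clusters below size are labelled
`unassigned`. The cut height sits near the top of the 1 − TOM scale on
purpose: at β = 6 even tightly co-expressed genes have pairwise TOM
dissimilarities around 0.9, while unrelated genes sit at ~1.0, so a cut
near 0.98 separates real modules from noise across a wide range of module
strengths. All three constants are config-exposed. This construction is a
defined, testable stand-in chosen by this package; it makes no claim to
reproduce any particular published module set, and dynamic tree cutting
and eigengene merging are intentionally out of scope.

## Synthetic data generators

The count generator emulates the study conditions directly: 24 samples in
six genotype groups (4/3/4/4/4/5), library sizes uniform on 8–12 M reads,
log-normal baseline abundances (σ = 1.8) over 5000 genes, and
negative-binomial noise with fixed dispersion 0.1 — a typical inbred-mouse
bulk RNA-seq value; a per-gene dispersion option is not provided because
the fixed-dispersion model is the simplest one the pipeline must recover.
A planted module of 100 genes is shifted +2 log₂ units (4-fold) in the
amyloid genotypes; driver knockout removes 80% of that shift, and
heterozygotes remove half of the knockout's effect (gene-dose). Setting
`het_effect_fraction = 0` gives the silent-het preset in which
heterozygous deletion leaves the transcriptome unchanged, mirroring the
observed near-silence of het animals.

The network generator builds a 1000-node DAG: a driver node with
downstream layers of sizes (25, 50, 100, 200) — a small first layer with
expanding deeper layers — each seeded with 25% planted-module genes
(93 of the 100 planted genes, leaving a ~1% background rate), each layer-i
node wired to 1–2 parents in layer i−1, and background genes in a sparse
forward-ordered random DAG unreachable from the driver. Layer membership
is exact by construction, which the tests exploit. The co-expression
generator uses a latent factor per module (loading 0.8, 5 modules of 60
genes among 500, 60 samples), with module 1 drawn from the planted DE
genes so module–signature enrichment has a planted positive.

All generators are pure functions of (config, seed); the planted module is
drawn from a seed-derived stream shared across generators, so counts,
network, and co-expression agree on the ground truth for a given seed.

**What passing these benchmarks shows — and does not.** The generators
plant clean, homogeneous effects: one module, one effect size, no
outlier samples, no batch structure, no correlated nulls in the count
model, and exact layer placement in the network. Recovery there
demonstrates the chain is implemented correctly and calibrated (FDR
control under the null, sensitivity at the planted effect size, driver
rank-1 recovery, module ARI), not that real tissue data with latent
confounders would behave as well. Covariate residualization is provided
for that purpose but is exercised only on synthetic covariates.

## Numerical choices

* Hypergeometric tails via `logsf`; probabilities below ~1e-308 underflow
  to 0 in the linear-scale accessor, with a log-scale accessor for
  magnitude comparisons.
* BH adjustment delegates to the standard step-up implementation and is
  order-invariant; adjusted values are capped at 1.
* Grubbs test: two-sided, single most-extreme observation per call, G
  compared to ((N−1)/√N)·√(t²/(N−2+t²)) at the α/(2N) Student-t quantile;
  constant vectors and n < 3 are errors rather than non-flags.
* Power uses the noncentral-t distribution exactly; α is read as
  two-sided.
* ΔΔCt assumes perfect base-2 amplification efficiency.
* TMM weight floor 1e-24 guards the degenerate one-gene library; zero
  shared genes with the reference is an error.
* Problem sizes in the test suite and acceptance script (5000-gene
  simulations, 20 replicates per benchmark, 10 000 Gaussian samples for
  outlier calibration) were chosen as the smallest sizes at which the
  binomial pass/fail bounds have comfortable margins.

## Known limitations

* The moderated model fits group means only; continuous covariates enter
  via prior residualization, not a joint design.
* Ortholog mapping is symbol-based (case-fold identity or an explicit
  two-column table); no homology database is consulted, and one-to-many
  mappings are dropped rather than resolved.
* Module detection uses a static cut; very unequal module strengths in
  one dataset may need a hand-tuned height.
* The union network is a simple edge union: no edge-confidence weighting
  or cohort-count thresholding.
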