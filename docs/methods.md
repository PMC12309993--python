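# Methods

## Problem setting

Bulk RNA-seq of heterogeneous tissue measures a mixture: the counts for
gene *g* in sample *i* reflect both how strongly each cell type
expresses *g* and how much RNA each type contributes to the sample.
When composition shifts between conditions (the motivating case is the
post-infarct heart: cardiomyocyte loss, fibroblast/macrophage gain),
standard differential expression attributes composition-driven changes
to gene regulation. `compshift` estimates composition from a
single-nucleus reference, converts it into well-behaved covariates, and
quantifies — by simulation with known ground truth — how much the
correction matters.

## Reference and signature

The reference arrives clustered and labeled; upstream processing
(ambient-RNA removal, doublets, integration, clustering, cell-type
annotation) is out of scope. Construction steps:

* **Duplicate symbols** are resolved by keeping the row with the
  highest mean expression across all nuclei (deterministic; first
  occurrence wins exact ties).
* **Gene universe**: the sorted intersection of reference and bulk
  genes; all downstream stages operate on it.
* **Marker selection** is one-vs-rest per cluster, after dropping
  clusters below `min_cluster_size` (default 500 nuclei; the desk-scale
  fixtures use smaller clusters and pass a smaller threshold). The test
  statistic is Welch's t on log1p(counts-per-10k) — a transparent,
  calibrated stand-in for the one-vs-all ranking of single-cell marker
  tools; under exchangeable clusters its p-values are uniform (checked
  by KS test in the suite). Per cluster, p-values are BH-adjusted
  across genes and the top *k* = 15 positive-effect genes are retained,
  ordered by adjusted p-value with ties broken by larger effect, then
  gene symbol. A gene winning in several clusters is assigned to the
  cluster with the smallest adjusted p-value.
* **Signature**: per-subject relative expression θ (type-wise gene
  shares over the universe; columns sum to 1) averaged across subjects;
  σ² is the across-subject sample variance (0, with a warning, for
  types seen in fewer than two subjects); cell sizes S_k are mean
  per-nucleus total counts. All three are stored restricted to the
  marker panel.

## Weighted deconvolution

Per sample, marker-gene relative abundances y (counts over the marker
rows, closed to the marker total so non-marker rows are irrelevant) are
fit by iteratively re-weighted NNLS on the design X_gk = S_k θ_gk:
unweighted NNLS initializes c; weights
`w_g = 1/(r_g² + Σ_k c_k² σ²_gk S_k² + ε)` down-weight genes that fit
poorly or whose signature varies across subjects; weighted NNLS
re-solves until the maximum relative change of c falls below `tol`.
Constants (ε = 1e-8, tol = 1e-6, max_iter = 1000) are package choices —
the upstream method's internals are not printed in its description —
and the fit degrades gracefully to residual-only weighting when σ² is
all zero (single-subject reference). Reported proportions
`p_k = c_k S_k / Σ_j c_j S_j` are RNA fractions; converting to cell
fractions would require dividing by S_k and renormalizing, which the
package deliberately does not do.

Properties enforced by tests: exact recovery of noiseless mixtures,
≥ 0.95 assignment for pure pseudo-bulks, invariance to per-sample
scaling and to non-marker rows, equivalence to plain NNLS when the
weighting loop is disabled, and monotonicity of the estimate in the
true fraction.

## Compositional covariates and Dirichlet regression

CLR coordinates are `z_k = ln(p_k/g(p))` with g the geometric mean;
rows sum to zero, which makes the full set collinear with an intercept
— models therefore take a subset of components (the simulation
benchmark uses the major type's coordinate; the factorial real-data
mode defaults to cardiomyocyte + fibroblast). Zeros are handled by the
standard compression `y* = (y(n−1) + 1/C)/n`, applied only when
boundary values are present; an additive pseudocount is available as an
alternative. PCA scores are computed on column-centered proportions;
the default single component follows the "PC1" usage.

Dirichlet regression uses the common parameterization
`α_ic = exp(x_i'β_c)` for every component. The log-likelihood is
maximized by L-BFGS with the analytic score
`∂ℓ/∂β_pc = Σ_i x_ip α_ic (ψ(Σ_c α_ic) − ψ(α_ic) + ln y_ic)`, started
from a moment estimate (pooled mean composition and a geometric-mean
precision) on the intercept. Standard errors come from the inverse
numerical observed information at the optimum; inference is Wald
(matching the per-term p-value style of the downstream use), and the
fit records the final score max-norm so optimizer failures are visible.
The implementation is cross-checked against the scipy Dirichlet/Beta
densities, and its calibration (type-I error ≈ 5%, parameter recovery
within 3 s.e. at n = 500) is part of the acceptance suite.

## Negative-binomial differential expression

Genes are filtered by the strict rule "more than 10 reads in at least
four samples". Size factors are median-of-ratios (library-size ratios
as a fallback when no gene is positive everywhere). Per gene, an NB
GLM with log link and `ln s_i` offset is fit by IRLS (max 100
iterations, relative log-likelihood tolerance 1e-8). Dispersion is
per-gene: a method-of-moments start from the Poisson fit, then a
profiled maximum-likelihood search over log φ (bounded 1e-8..100) with
warm-started IRLS refits; if the Poisson boundary beats the interior
optimum, φ = 0 is reported. There is no dispersion-trend or empirical-
Bayes shrinkage and no fold-change shrinkage — a documented
simplification of the DESeq2 machinery that keeps the estimator
self-contained; the guardrails are the closed-form Poisson-limit check,
agreement with a statsmodels Poisson GLM, null p-value uniformity (KS)
and a type-I error band in the acceptance tests. Inference is a Wald
test per contrast with BH adjustment across genes per contrast; failed
fits carry NaN and pass through the adjustment.

Two design modes are provided: treatment-coded genotype × treatment
with interaction (real-data style), and cell-means group coding
("~ 0 + group") for the simulation sweep, where each condition is
contrasted against the 50% baseline group. Compositional covariates
enter as additive columns in either mode.

## Simulation design

`make_fixture_reference` fabricates the clustered reference: five
cardiac cell types (cardiomyocyte, endothelial, fibroblast, macrophage,
pericyte/smooth-muscle), three subjects, 300 nuclei per type by
default. Gene means are a shared Gamma(2,1) base modulated per type by
a log-normal deviation with sd 1 on the natural-log scale — cell types
genuinely differ for most genes, as in real tissue. Five percent of
genes per type are planted markers: base expression floored at a
well-expressed level, boosted 12× in their own type and damped to 0.1×
elsewhere, so the planted in/out ratio (≥ 8-fold by construction) makes
the true marker set unambiguous. Types carry distinct expected totals
(cardiomyocytes ≈ 2.5× the others) so RNA-content factors are
exercised; nucleus counts are Poisson with subject-level (lognormal sd
0.15) and library-level (sd 0.3) jitter.

`simulate_experiment` mixes per-type profiles (summed cluster counts,
normalized — a read-sampling probability per gene) at target
proportions and draws one multinomial per sample, so column sums equal
`total_reads` exactly. The sweep varies cardiomyocytes 30–70% around a
50% baseline (81 conditions at the canonical 0.5% step); fibroblasts
and macrophages absorb the change in 0.6/0.4 anti-correlation, other
types keep their baseline shares, and Gaussian jitter (sd 0.005 on the
proportion scale) is added per replicate before clipping and closure.
Ten percent of genes are spiked: one log2 fold change per gene,
`z ~ N(0.58, 0.5)` (0.58 ≈ log2 1.5; a "double" mode fixes z = 1),
applied multiplicatively to every type profile and renormalized, in all
non-baseline conditions. Renormalization nudges non-spiked genes'
probabilities slightly; benchmark truth counts only designated spiked
genes as positives. Replicates per condition default to 4 (unreported
upstream) and everything is reproducible bit-for-bit from one seed.

What the generator does *not* emulate: UMI/read-level noise, gene
length and GC effects, batch structure, correlated gene modules within
a type, or condition-dependent cell states. Passing benchmarks
therefore demonstrate the estimators' behavior under a clean mixture
model, not robustness to every artifact of real data.

## Scaled-down benchmark sizes

The full-scale design (25e6 reads/sample, ~20k genes, 81 conditions)
is available by configuration but not the default. Two desk-scale
configurations are used:

* **Inflation check** (the headline number): 2,000 genes, 1e5
  reads/sample, 4 replicates at 40% and 50% cardiomyocytes, three
  seeds, analysis in 1000-gene batches. The unadjusted model calls
  ≈ 22% of tested genes DE (BH-FDR 0.05), reproducing the
  more-than-20% figure.
* **F1 benchmark**: 500-gene universe at 1e5 reads (≈ 200 reads/gene),
  the full 30–70% range at step 0.025 (17 conditions × 4 replicates =
  68 samples), five seeds, 500-gene batches. The denser grid is a
  deliberate choice: the covariate slope of the adjusted model is
  identified from *within-group* proportion variation pooled across
  conditions, and its variance scales as σ²_y/(N·σ²_within). With only
  a handful of conditions at desk read depth the slope is
  near-unidentifiable (the covariate is almost collinear with the group
  dummies) and the adjusted model loses all power; pooling the whole
  sweep — exactly what the original 81-group analysis does — restores
  identification at desk scale.

The benchmark covariate defaults to the major cell type's
representation (cardiomyocyte CLR/proportion or PC1), matching the
simulation model "expression ~ 0 + group + major cell type abundance";
two-component variants are available via `components=`. The grid edge
cm = 0.70 is a degenerate regime — the macrophage target proportion is
exactly zero there, compositions touch the simplex boundary and
log-ratio covariates lean on zero-compression — and the margin of the
CLR model over the unadjusted one is accordingly thinnest at that
point.

## Numerical choices and degenerate inputs

* BH adjustment: step-up with reverse cumulative-minimum monotonicity,
  NaN passthrough; equivalent to exhaustive enumeration (tested).
* NNLS inner solves use scipy's active-set solver; identical signature
  columns produce a warning and the solver's smallest-index preference.
* Linear predictors are clipped at ±30 before exponentiation in both
  GLM and Dirichlet likelihoods.
* All-zero bulk columns, empty gene filters, empty gene intersections,
  rank-deficient designs and off-grid baselines raise immediately with
  the offending names; under-filled marker clusters and single-subject
  variance degrade with warnings instead.
* Ties in marker ordering are broken deterministically (effect size,
  then gene symbol), so outputs are stable across platforms.

## Known limitations

* Dispersion is estimated per gene without shrinkage: with very few
  replicates per condition the Wald tests are slightly anticonservative
  for low-count genes; calibration is verified at the sizes the package
  defaults to.
* The deconvolution assumes the reference expression profiles apply to
  the bulk tissue (no condition-specific cell states) and estimates RNA
  fractions only.
* Dirichlet regression uses the common parameterization; precision
  modeling (alternative parameterization) and mixed effects are not
  implemented.
* ILR/ALR transforms are not provided; CLR subsets or PCA cover the
  covariate use case here.
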