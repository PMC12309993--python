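# compshift

Composition-aware differential expression for bulk RNA-seq of
heterogeneous tissue.

When the cellular makeup of a tissue changes between conditions — as it
does dramatically in the heart after myocardial infarction, where
cardiomyocytes die and fibroblasts and macrophages expand — bulk RNA-seq
confounds two signals: genes whose *regulation* changed, and genes whose
*host cell type* changed in abundance. `compshift` implements the full
workflow for separating them:

1. **Reference building** (`refbuild`): from a clustered single-nucleus
   count matrix, select per-cluster marker genes by one-vs-rest testing
   (top *k* = 15 by BH-adjusted p-value) and summarize each cell type as
   a signature: relative expression *θ_gk* (per-type gene shares),
   cross-subject variance *σ²_gk*, and RNA-content factors *S_k*.
2. **Deconvolution** (`deconv`): estimate per-sample RNA fractions *p_k*
   by marker-restricted, iteratively re-weighted non-negative least
   squares: solve `y_g ≈ Σ_k c_k S_k θ_gk` with `c_k ≥ 0`, weighting
   genes by `w_g = 1 / (r_g² + Σ_k ĉ_k² σ²_gk S_k² + ε)`, and report
   `p_k = c_k S_k / Σ_j c_j S_j` — the share of *transcripts* from each
   type, not the share of cells.
3. **Compositional statistics** (`compstats`): centered log-ratio
   coordinates `z_k = ln(p_k / g(p))` and principal-component scores of
   proportions for use as model covariates, plus Dirichlet regression
   (`α_c = exp(Xβ_c)`, Wald tests) for testing whether composition
   itself responds to genotype/treatment.
4. **Differential expression** (`diffexpr`): per-gene negative-binomial
   GLM `counts_gi ~ NB(μ_gi, φ_g)`, `ln μ_gi = ln s_i + x_i'β_g`, with
   median-of-ratios size factors, per-gene ML dispersion, the
   `>10 reads in ≥4 samples` filter, Wald contrasts and BH-FDR — run
   with or without compositional covariates.
5. **Simulation benchmark** (`simulate`, `benchmark`): pseudo-bulk
   mixtures at controlled cardiomyocyte proportions (30–70% around a
   50% baseline, anti-correlated fibroblast/macrophage changes,
   multinomial reads) with 10% of genes spiked by log-normal fold
   changes (mean log2FC 0.58 ≈ log2 1.5, sd 0.5), scored by the F1 of
   DE calls against the spiked truth.

The package is aimed at transcriptomics analysts who have a clustered
single-cell/nucleus reference and bulk counts and want to know how much
of their DE signal is compositional.

## Worked example

Everything runs from synthetic data; no downloads needed. From
`examples/05_differential_expression.py`:

```python
import compshift as cs

reference = cs.dedupe_genes(cs.make_fixture_reference(n_genes=1000, seed=0))
panel     = cs.select_markers(reference, k=15, min_cluster_size=100)
signature = cs.build_signature(reference, panel, list(reference.gene_ids))

design = cs.MixtureDesign(seed=3, cm_grid=cs.make_grid(0.30, 0.70, 0.025))
truth  = cs.simulate_experiment(reference, design)
counts = cs.filter_genes(truth.bulk_counts)

props  = cs.deconvolve_cohort(truth.bulk_counts, signature)
clr_cm = cs.clr_transform(props).values[["cardiomyocyte"]]
fits   = cs.compare_models(counts, truth.condition, truth.baseline_label,
                           {"unadjusted": None, "clr": clr_cm})
```

which prints:

```
990 genes tested; 99 carry a true fold change
  unadjusted  calls  308 genes DE (74 true positives, 234 composition-driven false positives)
  clr         calls   56 genes DE (43 true positives, 13 composition-driven false positives)
```

Read: the two groups differ by a 10-point cardiomyocyte shift plus 99
genuinely perturbed genes. Ignoring composition, 31% of all tested
genes look differentially expressed — mostly false positives created by
the abundance shift. With the cardiomyocyte CLR coordinate as a
covariate, the call list shrinks to near the true signal.

The other examples cover reference building (`01`), mixture simulation
(`02`), deconvolution accuracy (`03`, mean absolute proportion error
≈ 0.005), Dirichlet regression (`04`) and the full F1 benchmark (`06`).

A thin CLI mirrors the library:
`compshift build-ref | simulate | deconvolve | compstats | de | benchmark`
(see `compshift <command> --help`).

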