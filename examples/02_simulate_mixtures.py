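"""Simulate pseudo-bulk mixtures with known composition and spiked genes.

Bulk samples are multinomial draws from mixed cell-type expression
profiles; the cardiomyocyte proportion is swept around a 50% baseline
with fibroblasts/macrophages absorbing the change, and 10% of genes
carry log-normal fold changes (mean log2FC 0.58 ~ 1.5x) in every
non-baseline condition.
"""

import compshift as cs

reference = cs.dedupe_genes(cs.make_fixture_reference(n_genes=1000, seed=0))
design = cs.MixtureDesign(seed=1)

print(f"full sweep: {len(cs.design_sweep(design))} conditions "
      f"({design.cm_grid.min():.0%}-{design.cm_grid.max():.0%} cardiomyocytes)")

truth = cs.simulate_experiment(reference, design,
                               conditions=[0.40, 0.50, 0.60])
print(f"simulated {truth.bulk_counts.shape[1]} samples x "
      f"{truth.bulk_counts.shape[0]} genes, "
      f"{design.total_reads:,} reads each (column sums are exact)")
print(f"spiked genes: {len(truth.spiked_genes)} "
      f"(mean log2FC {truth.spiked_log2fc.mean():.2f})")
print("\ntrue RNA-fraction composition of the first sample per condition:")
first = truth.true_proportions.groupby(truth.condition).head(1)
print(first.round(3).to_string())
# these proportions are the simulation's ground truth; deconvolution
# (example 03) should recover them from the counts alone.
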