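"""Build a marker panel and deconvolution signature from a clustered
single-nucleus reference.

A synthetic reference stands in for a real snRNA-seq experiment: five
cardiac cell types, three subjects, planted type-exclusive markers.
"""

import compshift as cs

reference = cs.dedupe_genes(cs.make_fixture_reference(
    n_genes=1000, n_cell_types=5, n_subjects=3, n_nuclei_per_type=300,
    marker_frac=0.05, seed=0))
print(f"reference: {reference.n_genes} genes x {reference.n_nuclei} nuclei, "
      f"types: {reference.cell_types}")

panel = cs.select_markers(reference, k=15, min_cluster_size=100)
for cell_type, genes in panel.markers.items():
    print(f"  {cell_type:<14} top markers: {', '.join(genes[:5])} ...")

signature = cs.build_signature(reference, panel, list(reference.gene_ids))
print("\ncell-size factors (mean counts per nucleus; cardiomyocytes are "
      "large cells and contribute disproportionate RNA):")
print(signature.cell_sizes.round(0).to_string())
# theta columns hold each type's relative expression over the markers;
# sigma2 holds the across-subject variance that weights the deconvolution.
print(f"\nsignature: {signature.theta.shape[0]} marker genes x "
      f"{signature.theta.shape[1]} cell types")
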