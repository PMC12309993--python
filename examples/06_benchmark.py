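"""The full simulation benchmark: F1 of DE calls per covariate model.

Sweeps cardiomyocyte proportions 30-70%, runs DE for each covariate
representation, and scores calls against the spiked ground truth.
Higher F1 means better recovery of the genes that truly changed.
"""

import compshift as cs

reference = cs.dedupe_genes(cs.make_fixture_reference(n_genes=500, seed=11))
design = cs.MixtureDesign(cm_grid=cs.make_grid(0.30, 0.70, 0.05))

result = cs.run_benchmark(reference, design,
                          representations=("none", "raw", "clr", "pca"),
                          seeds=(1, 2, 3), batch_size=500)
summary = result.summary()
piv = summary.pivot_table(index="delta_cm", columns="representation",
                          values="mean_F1")
print("mean F1 per compositional shift (rows) and representation (cols):")
print(piv.round(3).to_string())
print("\nfraction of genes called DE by the unadjusted model "
      "(true rate of changed genes is 0.10):")
none = summary.query("representation == 'none'")
print(none.set_index("delta_cm")["mean_frac_DE"].round(3).to_string())
print("\nthe unadjusted model's call list grows with the compositional "
      "shift; the covariate models keep precision high, at some cost in "
      "power at the extreme shifts.")
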