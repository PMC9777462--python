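"""Generating a synthetic cohort and slicing it into sparsity tiers.

Draws a 1000-case cohort from the default ~30-analyte panel, applies the
tiered missingness, and shows per-analyte coverage plus the nested analyte
subsets at the four sparsity bounds.
"""

from labsieve import GeneratorConfig, analyte_coverage, generate_dataset, make_tiers

sparse, labels, truth = generate_dataset(GeneratorConfig(seed=7, n_cases=1000))

cov = analyte_coverage(sparse)
print("coverage of selected analytes:")
for name in ("troponin_t", "potassium", "urea", "ck_mb_mass"):
    print(f"  {name:15s} {cov[name]:.2f}")

print(f"\nprevalence: {sum(labels.labels.values()) / len(labels.labels):.3f}")

tiers = make_tiers(sparse)
for t in tiers:
    print(f"max missingness {t.max_missing_fraction:.0%}: {len(t.analyte_ids)} analytes")
# The tiers are nested: every analyte modeled under a strict missingness
# bound is also modeled under a looser one, and the fully observed troponin
# analog is in all of them.
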