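"""Housekeeping-gene detection and tiering.

A gene is a preliminary housekeeping gene (HKG) when its mean FPKM
exceeds 1 in every tissue. Stability is scored by the coefficient of
variation across tissue means and tiered by its quartiles; stable genes
are then split by expression level.
"""

import tissuexpr as tx

matrix, truth = tx.generate(tx.SynthConfig(seed=1))
summary = tx.summarize_by_tissue(tx.filter_min_expressed_samples(matrix))

result = tx.build_hkg_table(summary)
table = result.table
print(f"{len(table)} preliminary HKGs (mean FPKM > 1 in all 14 tissues)")
print(f"CV quartiles: Q1 = {result.q1:.4f}, Q3 = {result.q3:.4f}")
print(table.variability_tier.value_counts().to_string())

precision, recall = tx.truth_eval(result.genes, truth, "hkg")
print(f"\nplanted constitutive genes: recall {recall:.3f}, "
      f"precision {precision:.3f}")
# The few extra calls are background genes whose random tissue levels all
# landed above 1 FPKM — constitutive in this draw, so not really errors.

short = result.shortlist()
print(f"\n{len(short)} low-variability / high-expression genes "
      "(the strongest reference-gene candidates), top 5 by grand mean:")
print(short.sort_values("grand_mean_fpkm", ascending=False)
      [["cv", "grand_mean_fpkm"]].head().round(3).to_string())
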