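# tissuexpr

Multi-tissue RNA-seq expression profiling for bulk FPKM atlases: given a
genes × samples FPKM matrix and a sample → tissue design table, `tissuexpr`

- profiles per-tissue activity (the FPKM < 1 inactivity rule, replicate
  filters, tissue clustering, sample PCA);
- detects **housekeeping genes** (HKGs) — genes with mean FPKM > 1 in every
  tissue — and tiers them by the coefficient of variation
  CV = σ/μ across tissue means (low: CV ≤ Q1, high: CV ≥ Q3) and, for the
  stable tier, by expression level (1 < FPKM ≤ 10 < FPKM ≤ 50 < FPKM);
- detects **tissue-specific genes** (TSGs) by three joint criteria on
  tissue means: top-25% rank in the target tissue, mean > 50% of the sum of
  all other tissue means, and mean > 3× every other tissue mean; TSGs with
  mean FPKM < 1 in every non-target tissue are refined to **particular**
  TSGs;
- builds a **weighted co-expression network** from first principles:
  unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` with β chosen by the
  scale-free topology fit, topological overlap
  `TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
  module detection with eigengene merging (merge height 0.25, minimum
  module size 30), module–tissue correlation (tissue-specific at r > 0.65)
  and hub-gene calling at |GS| > 0.2 and |MM| > 0.8;
- runs **over-representation analysis** of any gene list against GMT gene
  sets (hypergeometric upper tail, Benjamini–Hochberg FDR);
- generates **synthetic atlases with planted truth** (constitutive,
  single-tissue, module-bound, background and inactive genes) so every
  stage can be validated end to end without any downloads.

It was written with the 14-tissue pig expression atlas setting in mind
(hundreds of SRA samples, FPKM-quantified), but nothing in it is
species-specific.

## Worked example

```python
import tissuexpr as tx

matrix, truth = tx.generate(tx.SynthConfig(seed=1))   # 3,740 genes × 70 samples
summary = tx.summarize_by_tissue(tx.filter_min_expressed_samples(matrix))
result = tx.build_hkg_table(summary)
print(len(result.table), "preliminary HKGs")
precision, recall = tx.truth_eval(result.genes, truth, "hkg")
```

prints (seed 1):

```
514 preliminary HKGs (mean FPKM > 1 in all 14 tissues)
CV quartiles: Q1 = 0.0659, Q3 = 0.0867
variability_tier
medium    256
high      129
low       129

planted constitutive genes: recall 1.000, precision 0.973
```

All 500 planted constitutive genes are recovered; the 14 extra calls are
background genes whose random per-tissue levels happened to land above
1 FPKM everywhere — constitutive in this draw, so not real errors. The
quartile tiering puts 129 genes (±1 of n/4) in each outer tier by
construction.

The `examples/` directory holds one short script per capability
(profiling, HKGs, TSGs, network, enrichment, full pipeline); each prints
its numbers with a line on what they mean. The same stages are available
from the shell:

```sh
tissuexpr synth --out run/ --seed 1          # synthetic atlas + all stages
tissuexpr all matrix.tsv design.tsv -o out/  # your own data
```

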