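"""Over-representation analysis of gene lists against gene sets.

The hypergeometric upper tail asks: drawing |query| genes from the
universe, how often would we hit at least the observed overlap with the
set? Here the per-tissue TSG lists are tested against a small collection
in which one set copies a planted tissue group.
"""

import tissuexpr as tx
from tissuexpr.io import GeneSet

matrix, truth = tx.generate(tx.SynthConfig(seed=1))
filtered = tx.filter_min_expressed_samples(matrix)
summary = tx.summarize_by_tissue(filtered)
table = tx.detect_tsg(summary)

universe = filtered.gene_ids
planted = truth[truth.role == "tsg"]
sets = [
    GeneSet("T01_program", "planted tissue-1 genes",
            frozenset(planted.loc[planted.target_tissue == "T01", "gene_id"])),
    GeneSet("T02_program", "planted tissue-2 genes",
            frozenset(planted.loc[planted.target_tissue == "T02", "gene_id"])),
    GeneSet("random_50", "no signal", frozenset(universe[::70])),
]

groups = {
    t: table.loc[table.is_tsg & (table.tissue == t), "gene_id"].tolist()
    for t in ("T01", "T02")
}
tables = tx.enrich_gene_groups(groups, sets, universe)

for name, result in tables.items():
    print(f"TSGs of {name}:")
    print(result[["set_id", "overlap", "set_size", "p", "fdr"]]
          .to_string(index=False))
    print()
# Each tissue's TSG list hits its own planted program with a vanishing p,
# while the random set stays near p = 1: the test separates real structure
# from chance overlap.
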