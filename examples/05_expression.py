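"""OR knockdown recovery and island-distance stratification.

Simulates negative-binomial counts (1000 genes, 300 ORs knocked down
4-fold in the perturbed condition, 3 vs 3 samples), normalises with
control-gene size factors, and asks: are ORs the most downregulated
genes, and does downregulation depend on distance to the nearest island?
"""

import numpy as np

from greekislands import (
    SimulationConfig,
    distance_to_island,
    fold_changes,
    simulate_annotation,
    simulate_counts,
    size_factors,
    topk_category_enrichment,
)

cfg = SimulationConfig(seed=1)
ann = simulate_annotation(cfg)
counts, condition, _ = simulate_counts(cfg, ann.genes)
counts = counts.loc[counts.sum(axis=1) > 0]

cls = {g.gene_id: g.gene_class for g in ann.genes}
factors = size_factors(counts,
                       control_genes=[g for g in counts.index if cls[g] == "non-OR"])
ctrl = [s for s in condition.index if condition[s] == "control"]
pert = [s for s in condition.index if condition[s] == "perturbed"]
fc = fold_changes(counts, factors, ctrl, pert)

med_or = fc.loc[[g for g in fc.index if cls[g] == "OR"]].log2fc.median()
med_non = fc.loc[[g for g in fc.index if cls[g] == "non-OR"]].log2fc.median()
print(f"median log2 fold change: OR {med_or:.2f} (truth -2.0), "
      f"non-OR {med_non:.2f} (truth 0.0)")

ranked = fc.sort_values("log2fc").index.tolist()
ors = {g for g in fc.index if cls[g] == "OR"}
overlap, p = topk_category_enrichment(ranked, 500, ors, set(fc.index))
print(f"of the 500 most downregulated genes, {overlap} are ORs "
      f"(hypergeometric p = {p:.2e})")

dist = distance_to_island([g for g in ann.genes if g.gene_class == "OR"], ann.islands)
or_fc = fc.log2fc.reindex(dist.index)
near = or_fc[dist < 1e6].median()
far = or_fc[dist == 1e8].median()
print(f"median OR log2fc within 1 Mb of an island: {near:.2f}; "
      f"on island-free chromosomes (distance sentinel 1e8): {far:.2f}")
print()
print("Downregulation is uniform across island distance — the knockdown in")
print("this simulation acts on every OR, matching the distance conventions")
print("(1 = overlapping an island, 1e8 = no island on the chromosome).")
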