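"""Co-binding enrichment from published peak tallies.

In mature olfactory sensory neurons, 63 of 114 Lhx2 consensus peaks inside
OR clusters overlap an Ebf peak, against a genome-wide rate of 4729/16197;
for Ebf, 63 of 65 in-cluster peaks overlap Lhx2 against 4729/8959.  The
exact one-sided binomial test quantifies how unlikely those in-cluster
rates are under the genome-wide null.
"""

from greekislands import cobinding_enrichment

lhx2 = cobinding_enrichment(k_in=63, n_in=114, k_bg=4729, n_bg=16197,
                            alternative="greater")
ebf = cobinding_enrichment(k_in=63, n_in=65, k_bg=4729, n_bg=4729 + 4230,
                           alternative="greater")

print(f"Lhx2: {lhx2}")
print(f"Ebf : {ebf}")
print()
print("Both p-values are far below any conventional threshold: co-binding")
print("is dramatically over-represented inside OR clusters, the defining")
print("statistical signature of the Greek Islands.")
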