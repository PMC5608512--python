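"""Composite-motif scoring and the Lhx2/Ebf spacing grammar.

Island enhancers carry an Lhx2 homeodomain site immediately adjacent to an
Ebf site.  A single composite matrix (Lhx2 + 0 bp spacer + Ebf) scores
juxtaposed sites far higher than dispersed half-sites, and the closest
Ebf-Lhx2 pair distance separates the two geometries sharply.
"""

import numpy as np

from greekislands import (
    SimulationConfig,
    assemble_composite,
    best_match_score,
    build_logodds,
    default_ebf_pfm,
    default_lhx2_pfm,
    ks_one_sided,
    pair_distances_by_region,
    scan_sequence,
    simulate_sequences,
)

cfg = SimulationConfig(seed=1)
ss = simulate_sequences(cfg)
labels = ss.truth.set_index("region_id")["label"]

lhx2, ebf = default_lhx2_pfm(), default_ebf_pfm()
lom = build_logodds(assemble_composite(lhx2, ebf, spacer_bp=0))
print(f"composite consensus: {assemble_composite(lhx2, ebf, 0).consensus} "
      f"(max score {lom.max_score:.1f})")

scores = {r: best_match_score(s, lom) for r, s in ss.sequences.items()}
pos = [scores[r] for r in scores if labels[r] == "composite"]
neg = [scores[r] for r in scores if labels[r] == "dispersed"]
print(f"median best score, planted composites: {np.median(pos):.1f}")
print(f"median best score, dispersed sites:    {np.median(neg):.1f}")
acc = (sum(s > 10 for s in pos) + sum(s <= 10 for s in neg)) / (len(pos) + len(neg))
print(f"classification accuracy at the stringent threshold 10: {acc:.1%}")

lom_l, lom_e = build_logodds(lhx2), build_logodds(ebf)
hits_l, hits_e = [], []
for rid, s in ss.sequences.items():
    hits_l += scan_sequence(s, lom_l, 5.0, rid)
    hits_e += scan_sequence(s, lom_e, 5.0, rid)
dists = pair_distances_by_region(hits_e, hits_l)
comp = [d for r, d in dists.items() if labels[r] == "composite"]
disp = [d for r, d in dists.items() if labels[r] == "dispersed"]
d_stat, p = ks_one_sided(comp, disp, "smaller")
print(f"median closest-pair distance: composite {np.median(comp):.0f} bp, "
      f"dispersed {np.median(disp):.0f} bp")
print(f"one-sided KS (composite distances smaller): D={d_stat:.2f}, p={p:.2e}")
print()
print("Composite regions sit at distance 0 (the two half-sites touch);")
print("dispersed controls sit 40-120 bp apart, and the one-sided KS test")
print("rejects equality overwhelmingly.")
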