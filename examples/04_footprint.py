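"""Transposase insertion footprint at occupied motifs.

Each ATAC fragment end marks a transposase insertion; ends are shifted
4 bp toward the fragment interior to the true insertion site.  Where a
protein occupies its motif, insertions are locally depleted — a dip in
the 5 bp-binned insertion density centered on the motif.
"""

from greekislands import (
    SimulationConfig,
    end_density_profile,
    shift_to_insertions,
    simulate_fragments,
)

cfg = SimulationConfig(seed=1)  # depletion 0.5 within ±10 bp of 500 sites
frags, centers = simulate_fragments(cfg)
sites = shift_to_insertions(frags)
print(f"{len(frags.fragments)} fragments -> {len(sites.sites)} insertion sites "
      f"({sites.n_clamped} too short to shift)")

profile = end_density_profile(sites, centers, flank_bp=cfg.site_flank, bin_bp=5)
central = profile.loc[profile.bin_start.abs() <= 5, "mean"].mean()
flank = profile.loc[profile.bin_start.abs() >= 50, "mean"].mean()
print(f"mean insertions per 5 bp bin: central {central:.2f}, flank {flank:.2f}")
print(f"central/flank ratio: {central / flank:.2f}")
print()
print("The ratio tracks the simulated occupancy depletion (0.5): bound")
print("motifs shield their DNA from insertion, carving a footprint into")
print("the accessibility signal.")
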