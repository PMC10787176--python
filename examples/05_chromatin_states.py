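"""Promoter chromatin-state diversity, X versus autosomes.

Simulates chromHMM-style segmentations for 30 epigenomes where X-linked
promoters draw from larger state palettes (12 vs 9 states), then counts the
distinct states each promoter displays across all epigenomes -- the
regulatory-variability signature that accompanies high tissue specificity.
"""

import xdosage as xd

params = xd.SimulationParams(
    n_autosomal_genes=300, n_x_genes=100, n_tissues=1, n_stages=2,
    palette_size_x=12, palette_size_a=9, seed=5,
)
annotation = xd.simulate_genome(params)
segmentations = xd.simulate_chromatin(annotation, params, n_epigenomes=30)
result = xd.promoter_state_analysis(annotation, segmentations)

div = result["diversity"]
print(f"median distinct states per promoter: X = {div['median_x']:.0f}, "
      f"autosomes = {div['median_autosomes']:.0f} "
      f"(rank-sum p = {div['p']:.2e})")

frac = result["base_fractions"]
x_frac = frac[frac["chromosome"] == "X"].nlargest(3, "fraction")
print("top states on X promoters (fraction of annotated bases):")
for row in x_frac.itertuples():
    print(f"  {row.state:<12} {row.fraction:.3f}")

print("\nThe X-autosome gap in distinct-state counts recovers the simulated")
print("palette difference; per-chromosome base fractions always sum to 1.")
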