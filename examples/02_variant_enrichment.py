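"""Compare variant density between PSD and NSD genomic regions.

Pathogenic variants in the synthetic universe are planted three-fold
denser in pathway-specific domain regions; neutral variants are uniform.
The normalized variation rate (NVR = per-class density / background
density) should therefore exceed 1 for pathogenic variants in PSDs and
sit near 1 everywhere for neutral variants.
"""

import psdnet as ps

universe = ps.generate_universe(ps.UniverseConfig(seed=0))
result = ps.run_pipeline(
    universe.annotations, universe.pathways, universe.gold_domain_pathway
)

# label the domain regions with the classified PSD/NSD calls
regions = universe.region_set(result.specificity.domain_labels)
counts = ps.count_variants_in_regions(universe.variants, regions)
report = ps.compute_nvr(counts, regions.total_nt)

print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
for cls in counts.index:
    p = ps.nvr_difference_test(counts, regions.total_nt, cls)
    print(f"{cls}: two-sided binomial p for the PSD-NSD difference = {p:.3g}")
print("\nNVR > 1 in PSD rows for the pathogenic class (and ~1 for neutral)")
print("reproduces the planted enrichment; the binomial test conditions on")
print("the total in-domain variant count against the PSD nucleotide share.")
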