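"""Score domain-pathway specificity and classify PSDs on a synthetic universe.

Generates the default synthetic universe (200 proteins, 80 domains, 10
pathways, 40 planted pathway-specific domains), runs the full chain —
domain profiles -> rarity weights -> weighted mutual information ->
LLS calibration -> positive-LLS co-pathway network -> PPA/DPA/Gini/PS ->
PSD/NSD classification — and reports how well the planted domains are
recovered.
"""

import psdnet as ps

universe = ps.generate_universe(ps.UniverseConfig(seed=0))
result = ps.run_pipeline(
    universe.annotations, universe.pathways, universe.gold_domain_pathway
)

sr = result.specificity
print(f"proteins x domains : {result.matrix.shape}")
print(f"positive-LLS edges : {len(result.network.edges)} of {len(result.pairs)} pairs")
print(f"associations scored: {len(sr.table)}")
print(f"PS threshold       : {sr.chosen_ps_threshold:.4f} at rank {sr.chosen_rank}")
print(f"PSDs / NSDs        : {len(sr.psd_domains)} / "
      f"{(sr.domain_labels == 'NSD').sum()}")

print("\nTop 5 domain-pathway associations (highest PS):")
print(sr.table.head(5)[["domain_id", "pathway_id", "dpa", "gini", "ps"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

planted = universe.planted_domains
psd = sr.psd_domains
tp, fp, fn = len(planted & psd), len(psd - planted), len(planted - psd)
f1 = 2 * tp / (2 * tp + fp + fn)
print(f"\nplanted-domain recovery: {tp} true / {fp} false positives, F1 = {f1:.3f}")
print("A high F1 means the top-ranked PS associations single out exactly the")
print("domains that were planted as pathway-specific in the simulation.")
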