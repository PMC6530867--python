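"""Rescue GWAS candidates of moderate significance with disease PSDs.

SNPs are assigned to genes within 10 kb; genes with a moderately
significant SNP (1e-7 < p <= 1e-3) form the candidate pool.  Pathways
overlapping the seed disease genes (Fisher p < 0.01, >= 5 members) mark
their significantly associated PSDs as disease PSDs, and a candidate is
selected when it carries at least three of them (the GWAS∩PSD set).
Precision is evaluated against held-out validation disease genes.
"""

import psdnet as ps

universe = ps.generate_universe(ps.UniverseConfig(seed=0))
result = ps.run_pipeline(
    universe.annotations, universe.pathways, universe.gold_domain_pathway
)

assignments = ps.assign_snps_to_genes(universe.gwas, universe.genes)
moderate = ps.select_moderate_genes(assignments)
universe_size = len(universe.genes)
disease_psds, disease_pathways = ps.derive_disease_psds(
    universe.seed_genes, universe.pathways, result.specificity, universe_size
)
gene_min_p = {g: float(df["p"].min()) for g, df in assignments.items()}
table = ps.select_candidates(
    moderate, universe.gene_domains(), disease_psds, gene_min_p=gene_min_p
)
precision, baseline = ps.evaluate_precision(
    table, universe.validation_genes, universe_size
)
n_sel = int(table["selected"].sum())
gwas_only = sorted(moderate, key=lambda g: (gene_min_p[g], g))[:n_sel]
gwas_precision = len(set(gwas_only) & universe.validation_genes) / n_sel

print(f"moderate-significance genes : {len(moderate)}")
print(f"disease pathways            : {sorted(disease_pathways)}")
print(f"disease PSDs                : {len(disease_psds)}")
print(f"selected (GWAS∩PSD set)     : {n_sel}")
print(f"precision  GWAS∩PSD         : {precision:.3f}")
print(f"precision  GWAS-rank only   : {gwas_precision:.3f}")
print(f"precision  random baseline  : {baseline:.3f}")
print("\nThe PSD filter concentrates true disease-pathway genes among the")
print("selected candidates, beating both a pure GWAS ranking of equal size")
print("and the random expectation |validation| / |all genes|.")
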