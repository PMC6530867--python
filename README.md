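# psdnet

Network-based **pathway-specificity scoring of protein domains**.

Protein domains differ in how tightly they are tied to individual
biological pathways: some ("pathway-specific domains", PSDs) occur almost
exclusively in the proteins of one or a few pathways, while others are
generic building blocks found everywhere.  `psdnet` quantifies this with a
per-(domain, pathway) **Pathway Specificity (PS)** score, classifies
domains into PSDs and non-specific domains (NSDs), and applies the
classification to two downstream questions:

* are disease-associated genetic variants **denser in PSD genomic
  regions** than in NSD regions (normalized variation rates with exact
  binomial tests)?
* can PSDs **rescue GWAS candidate genes** of moderate significance
  (10⁻⁷ < p ≤ 10⁻³) that single studies cannot call?

The package is aimed at computational biologists working with
protein-domain annotations (InterPro-style), pathway gene sets
(GOBP-style GMT files), and variant/GWAS summary tables.

## The scoring scheme

1. **Domain profiles.** Each protein is a Boolean vector over the domain
   universe (c<sub>ij</sub> = 1 iff protein *i* contains domain *j*).
   Each domain receives a rarity weight
   ω<sub>j</sub> = (Σ<sub>kl</sub> c<sub>kl</sub>) / (Σ<sub>k</sub> c<sub>kj</sub>) ≥ 1,
   so rare domains — the ones plausibly tied to specific processes —
   weigh more.

2. **Weighted mutual information (WMI).** Protein pairs are scored by the
   mutual information of their profiles under the ω-weighted probability
   measure: I<sub>ω</sub>(X,Y) = H<sub>ω</sub>(X) + H<sub>ω</sub>(Y) −
   H<sub>ω</sub>(X,Y), in nats.

3. **Log-likelihood scores (LLS).** Pairs are walked in descending WMI
   order in bins; each bin's LLS = ln[(P(L|E)/P(¬L|E)) / (P(L)/P(¬L))]
   is estimated from gold-standard co-pathway pairs (proteins annotated
   to a common pathway).  Edges with positive LLS form the **co-pathway
   network**.

4. **Protein-pathway association (PPA).** s<sub>i</sub>(f) sums the LLS
   of protein *i*'s edges into pathway *f*'s members; the positive sums
   are modelled as Pareto(s<sub>min</sub>, α) with
   α = max(1, 1 + n/Σln(s<sub>i</sub>/s<sub>min</sub>)), and
   PPA<sub>i</sub>(f) = 1 − (s<sub>min</sub>/s<sub>i</sub>)<sup>α</sup>.

5. **Domain-pathway association (DPA) and specificity.**
   DPA<sub>j</sub>(f) is the mean PPA of the domain's carriers;
   GI<sub>j</sub> = 1 − Σ<sub>f</sub>(DPA<sub>j</sub>(f)/ΣDPA)² is the
   Gini impurity of the domain's pathway distribution, and
   **PS<sub>j</sub>(f) = (1 − GI<sub>j</sub>) × DPA<sub>j</sub>(f)**.

6. **PSD/NSD classification.** Associations are ranked by PS; consecutive
   rank segments are tested for enrichment of curated (InterPro2GO-style)
   gold-standard domain-pathway pairs with one-sided Fisher's exact
   tests, and the cutoff is the end of the last contiguous significant
   segment.  Domains in the top-ranked associations are PSDs.

Because the published analyses depend on versioned external databases, a
first-class synthetic-universe generator (`psdnet.simulate`) produces all
inputs — annotations, GMT pathway sets, gold standards, domain regions
(BED), variants, interaction edges, GWAS summaries — with planted
pathway-specific domains, so the whole pipeline is testable end to end
against known ground truth.

## Worked example

```python
import psdnet as ps

universe = ps.generate_universe(ps.UniverseConfig(seed=0))
result = ps.run_pipeline(
    universe.annotations, universe.pathways, universe.gold_domain_pathway
)
```

Running `python examples/01_score_pathway_specificity.py` prints:

```
proteins x domains : (200, 80)
positive-LLS edges : 3000 of 19900 pairs
associations scored: 800
PS threshold       : 0.0853 at rank 48
PSDs / NSDs        : 40 / 40

Top 5 domain-pathway associations (highest PS):
domain_id pathway_id    dpa   gini     ps
      D05      PWY05 0.9390 0.8459 0.1447
      D18      PWY08 0.9753 0.8597 0.1369
      D28      PWY08 0.9891 0.8635 0.1350
      D08      PWY08 0.9392 0.8577 0.1336
      D02      PWY02 0.9924 0.8683 0.1307

planted-domain recovery: 40 true / 0 false positives, F1 = 1.000
```

The 40 domains planted as pathway-specific are exactly the 40 classified
PSD: each top association pairs a planted domain with its own pathway
(D05→PWY05, D02→PWY02, ...), with high DPA (strong network connectivity
into the pathway) and comparatively low Gini (concentrated on one
pathway).  The other examples show variant enrichment
(`02_variant_enrichment.py`: NVR ≈ 1.98 in PSDs vs 0.67 in NSDs for
pathogenic variants, binomial p ≈ 10⁻⁶²; ≈ 1 for neutral variants),
interaction-degree Domain Ratios (`03`), and GWAS candidate selection
(`04`: GWAS∩PSD precision 0.45 vs 0.28 for a GWAS-only ranking of equal
size and 0.15 random baseline).

## Command line

Every stage is also a subcommand:

```bash
psdnet simulate  --seed 1 --out-dir fixtures/
psdnet profiles  --annotations fixtures/annotations.tsv --out-matrix m.tsv --out-weights w.tsv
psdnet network   --matrix m.tsv --weights w.tsv --pathways fixtures/pathways.gmt --out net.tsv
psdnet score     --net net.tsv --matrix m.tsv --pathways fixtures/pathways.gmt \
                 --gold fixtures/gold_domain_pathway.tsv --rank-grid-step 16 --out ps.tsv
psdnet nvr       --regions fixtures/domain_regions.bed --variants fixtures/variants.tsv --out nvr.tsv
psdnet domain-ratio --edges fixtures/interaction_edges.tsv --labels ps.tsv --bins 4 --out ratio.tsv
psdnet prioritize --gwas fixtures/gwas.tsv --genes fixtures/genes.bed --ps ps.tsv \
                 --pathways fixtures/pathways.gmt --annotations fixtures/annotations.tsv \
                 --seed fixtures/seed_genes.txt --validate fixtures/validation_genes.txt --out prior.tsv
```

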