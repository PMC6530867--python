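# Methods

## Model and procedure

`psdnet` scores how specifically each protein domain is associated with
each biological pathway, using only Boolean domain-occurrence profiles
and pathway gene sets.  The chain of quantities:

**Rarity weights.** For the occurrence matrix c (proteins × domains),
domain *j* gets ω<sub>j</sub> = (total occurrences)/(occurrences of *j*).
The weight is the reciprocal of the domain's occurrence frequency,
normalized so a domain present in every protein has the smallest weight.
Motivation: domain occurrence is heavy-tailed in real proteomes, and rare
domains carry more information about specific processes than ubiquitous
folds.  Invariant: ω<sub>j</sub> × (column sum) equals the matrix total
exactly.

**Weighted mutual information.** Protein profiles are compared by mutual
information computed under the probability measure that gives domain *j*
mass ω<sub>j</sub>/Σω.  All entropies use natural logarithms; the choice
of base only rescales scores and the downstream calibration uses rank
order only.  The implementation computes the all-pairs WMI matrix from a
single matrix product (the pairwise mass on the (1,1) cell is
(C·diag(ω))Cᵀ/Σω; the other three joint cells follow from the marginals),
which makes the 19,900-pair default instance essentially instantaneous
and scales comfortably to tens of thousands of proteins.

**LLS calibration.** Pairs sorted by descending WMI (ties broken
lexicographically so binning is deterministic) are grouped in bins of
`bin_size` (default 1,000).  A bin's log-likelihood score is
ln[(pos/neg)/(P(L)/P(¬L))] where pos/neg count the bin's gold-standard
members — pairs of proteins co-annotated (positive) or annotated but
never co-annotated (negative) to the pathway sets — and the prior odds
use all gold pairs.  Pairs that are not in the gold standard still
inherit their bin's LLS: the Bayesian statistic can only be estimated
from gold members, but applies to every pair ranked alike.  Bins whose
gold members are one-sided merge forward (equivalent to a larger bin);
a deficient or partial trailing bin merges backward so the
high-confidence head of the ranking is never diluted.  Only edges with
LLS > 0 enter the co-pathway network.

**Pareto-transformed association scores.** For pathway *f*, protein *i*'s
link sum s<sub>i</sub>(f) adds the LLS of its edges into *f*'s member
set.  Positive sums are modelled as Pareto: s<sub>min</sub> is the
minimum observed positive sum and the shape is
α = 1 + n·[Σ ln(s<sub>i</sub>/s<sub>min</sub>)]⁻¹, lower-clamped at 1.
PPA<sub>i</sub>(f) = 1 − (s<sub>min</sub>/s<sub>i</sub>)<sup>α</sup>;
proteins with zero sum get PPA 0 directly (they never enter the fit,
since ln(0/s<sub>min</sub>) is undefined and a zero sum carries no
evidence).  Two numerical notes:

* As written, the shape estimate is 1 + (positive term), so the clamp at
  1 is a guard that the estimate approaches only in the limit of extreme
  log-spread; it can never be violated.  The clamp is kept because the
  intent is a hard floor on the tail exponent, and the guard makes that
  explicit whatever estimator variant is substituted.
* When all positive sums are equal the log-spread is zero; α is then
  reported as +∞ and PPA is 0 at the boundary (the continuity limit), so
  no overflow path exists.
* PPA is invariant to rescaling all LLS by a positive constant
  (s/s<sub>min</sub> is scale-free), which the tests verify.

**DPA, Gini, PS.** DPA<sub>j</sub>(f) is the mean PPA over the carriers
of domain *j* that appear in the network (domains with no such carrier
are excluded and logged).  The Gini impurity
GI<sub>j</sub> = 1 − Σ<sub>f</sub>(share)² of the domain's DPA row is 0
when a single pathway holds all the mass and approaches 1 − 1/F for an
even spread over F pathways; an all-zero row has undefined Gini and is
assigned PS 0 everywhere.  PS = (1 − GI) × DPA ranks all (domain,
pathway) associations.

**PSD/NSD classification.** The ranked association list is scanned in
consecutive segments of `rank_grid_step` associations.  Each segment is
tested for enrichment of gold-standard domain-pathway positives
(one-sided Fisher's exact test on (in-segment vs outside) ×
(gold-positive vs gold-negative), over the assessable associations — the
ones present in the gold positives or negatives).  The cutoff is the end
of the last contiguous significant segment from the top; this mirrors
dividing the associations into a top block that significantly overlaps
the curated standard and a remainder that does not, and it degrades
correctly in both extreme regimes: sharply concentrated gold positives
stop the scan right after the signal ends, and uniformly scattered
positives leave the first segment non-significant so every domain stays
NSD.  (A "largest k where top-k vs below-k is significant" rule does not
have this property: once the top block holds all positives, top-k versus
below-k remains significant for arbitrarily large k.)  Associations tied
in PS with the cutoff association are included.  Domains appearing in at
least one top association are PSDs; all other scored domains are NSDs.
The pipeline's default grid step is ~2 % of the association count, the
same grid-to-table ratio as scanning a ~50,000-row table in steps of
1,000.

**Variant enrichment.** Domain regions (BED convention: 0-based,
half-open) are merged within each label before counting, so overlapping
annotations are not double-counted; variant positions are 1-based (VCF
convention) and converted at comparison.  VR = variants/nucleotide per
(variant class, domain class); BVR pools both domain classes; NVR =
VR/BVR.  The nt-weighted mean of the two NVRs is identically 1 (tested
to 1e−12).  Significance: exact two-sided binomial test of the PSD count
among in-domain variants against p₀ = nt<sub>PSD</sub>/nt<sub>total</sub>
— i.e. conditioning on the total in-domain count, the natural null for a
density comparison.  Mutation classes (pathogenic, neutral, edgetic,
quasi-null, quasi-WT, ...) all flow through the same machinery via the
class label; strand is ignored.

**Interaction-degree Domain Ratio.** Degree counts distinct interaction
partners (not interaction multiplicity).  Domains are partitioned into
bins of similar *size* along the degree axis — degree distributions are
heavy-tailed, so equal-width intervals would give wildly uneven groups —
with equal-degree ties always kept together.  Each bin reports
log₂[(PSD share)/(NSD share)], antisymmetric under swapping the two
classes (tested).

**GWAS prioritization.** SNPs map to every gene whose body ±10 kb
(inclusive bounds) contains them; a gene is a moderate candidate when at
least one of its SNPs has 10⁻⁷ < p ≤ 10⁻³ (strict lower, inclusive upper
bound).  Pathways with ≥ 5 members whose overlap with the seed disease
genes is hypergeometrically significant (one-sided, p < 0.01, within the
gene universe) are disease pathways; the disease-PSD set is the union of
PSDs whose significant associations involve any disease pathway (not
just their top-ranked one).  A moderate candidate is selected when it
carries ≥ 3 disease PSDs.  Precision = selected ∩ validation / selected;
baseline = |validation|/|universe|.  Per-gene GWAS strength is summarised
as the minimum SNP p-value.

## Synthetic universe

`psdnet.simulate.generate_universe` produces every input format from a
single seeded generator, with ground truth retained.  Defaults
(`UniverseConfig`): 200 proteins, 80 domains, 10 pathways, carrier rate
0.8, background rate 0.05, 3× pathogenic-variant enrichment in planted
regions, 1,000 variants per class, 300-nt domain regions, GWAS signal
strength 0.8.

Design choices that matter:

* **Half the domains are planted** (4 per pathway): pathway-specific
  domains are roughly half the annotated domain universe in real
  proteomes, and several specific domains per pathway are what make
  co-pathway protein pairs distinguishable — with a single planted
  domain per pathway at this scale, the WMI signal of one shared rare
  domain is about one standard deviation of the shared-decoy noise
  (≈ √m<sub>decoy</sub>·T/n of shared weighted mass), unrecoverable in
  principle.
* **Decoy domains are prevalent.** Decoys get occurrence rates of
  background_rate × log-uniform(4, 12) (capped at 0.9), so domain
  occurrence is heavy-tailed and the planted domains sit in the rare
  tail, which is precisely the regime the rarity weighting assumes
  (rare ⇒ specific, prevalent ⇒ generic).  Making decoys rarer than the
  planted domains inverts the weight hierarchy and destroys recovery.
* **Balanced pathways.** Proteins are dealt round-robin into pathways
  (~20 members each) with a 5 % chance of a second membership;
  multinomial assignment produces pathways too small to recover at this
  scale.
* **Genome layout.** One synthetic chromosome; fixed-length (20 kb),
  non-overlapping genes spaced 50 kb apart (so ±10 kb SNP windows cannot
  straddle neighbours by construction); domain regions tile the gene
  body in 300-nt slots.  This exercises all coordinate logic without any
  real genome data.
* **Variants.** Pathogenic variants choose a region with probability
  proportional to length × (enrichment factor if the domain is planted),
  then a uniform position; neutral variants are length-uniform.
* **GWAS.** Genes in the three designated disease pathways carry one
  moderate-band SNP (p log-uniform in 10⁻⁶..10⁻³) with probability 0.8;
  all other genes with probability 0.4 — the moderate band is mostly
  noise in real GWAS, and that noise is what the PSD filter is supposed
  to remove.  Remaining SNP p-values are uniform.
* **Gold standards.** Domain-pathway positives are exactly the planted
  pairs; negatives pair the gold-covered domains (all planted plus half
  the decoys, mirroring partial curation coverage) with their
  non-associated pathways.
* **Interaction edges** are drawn with heavy-tailed endpoint
  probabilities assigned independently of pathway structure, so degree
  heterogeneity exists but the Domain Ratio has no planted signal.

What the generator does **not** emulate: real InterPro domain
architecture statistics and domain co-occurrence along proteins, linkage
disequilibrium and realistic GWAS p-value distributions, genome-scale
coordinates, hierarchical (GO-DAG) pathway structure, and annotation
noise in the gold standards.  Passing the recovery tests therefore shows
the scoring chain is implemented correctly and is identifiable under its
own modelling assumptions — not that those assumptions hold in any
particular real dataset.

## Problem sizes and determinism

The default test and acceptance runs use the 200×80×10 universe
(19,900 protein pairs, 800 associations), chosen so a full pipeline run
takes well under a second and the complete suite including the
1,000-case invariant sweeps finishes in tens of seconds.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
the same config regenerates byte-identical files, and all orderings are
made deterministic (lexicographic tie-breaks in the WMI sort and the PS
ranking).

One statistical subtlety encoded in the tests: the per-bin LLS estimator
ln(K/(n−K)) of a binomial count carries a Jensen bias of
(2p−1)/(2np(1−p)) + O(1/n²), so under label permutation the mean LLS
centres on that bias, not exactly on zero; the permutation test accounts
for it analytically.

## Known limitations

* PPA compresses toward 1 for well-connected proteins (the Pareto CDF is
  very concave for α near 1), so DPA differences in dense networks are
  small in absolute terms; the classification depends on ranks, not on
  absolute PS gaps.
* Proteins annotated to a pathway are not excluded from their own
  PPA computation (no leave-one-out); this is a known circularity,
  switchable via `exclude_self_pathway`.
* Gold-standard negatives for protein pairs are exhaustive
  (all annotated, never co-annotated pairs); for very large universes a
  sampling cap would be needed.
* The Fisher scan applies no multiple-testing correction across
  segments; the contiguity requirement is what controls the null case.
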