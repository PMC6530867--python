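"""Synthetic universe with planted pathway-specific domains.

The generator emulates the statistical structure the scoring scheme
assumes: each pathway's member proteins are enriched for one (or a few)
"planted" domains, all proteins carry every domain at a low background
rate, pathogenic variants fall preferentially into planted-domain genomic
regions, and GWAS p-values for genes in designated disease pathways are
shifted into the moderate-significance band.  Every output is produced in
the plain-text formats the other modules consume, and the ground truth
(which domains are planted, which pathways are disease pathways, which
genes are seed vs validation disease genes) is retained so recovery can be
scored.

All randomness flows from ``UniverseConfig.seed`` through a single
``numpy`` generator, so a config regenerates its universe exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .specificity import GoldStandardDomainPathwayPairs
from .variants import DomainRegionSet

__all__ = ["UniverseConfig", "SyntheticUniverse", "generate_universe", "generate_worked_example"]

CHROM = "chrS1"
GENE_SPAN = 50_000  # spacing between gene starts; > gene length + 2 * SNP window
GENE_LENGTH = 20_000


@dataclass(frozen=True)
class UniverseConfig:
    """Knobs of the synthetic universe.

    Rates are probabilities in [0, 1]; ``planted_fraction`` of the domains
    are pathway-specific (assigned round-robin to pathways), the rest are
    decoys carried only at ``background_rate``.
    """

    n_proteins: int = 200
    n_domains: int = 80
    n_pathways: int = 10
    planted_fraction: float = 0.5
    carrier_rate: float = 0.8
    background_rate: float = 0.05
    variant_enrichment_factor: float = 3.0
    region_length_nt: int = 300
    n_variants: int = 1000
    gwas_signal_strength: float = 0.8
    seed: int = 0
    # secondary structure
    second_pathway_rate: float = 0.05   # chance a protein joins a second pathway
    # decoy (generic) domains are more prevalent than planted ones: their
    # per-protein occurrence rate is background_rate times a log-uniform
    # multiplier in this range (capped at 0.9), putting planted domains in
    # the rare tail of a heavy-tailed occurrence distribution
    decoy_prevalence_multiplier: tuple[float, float] = (4.0, 12.0)
    gold_decoy_fraction: float = 0.5    # fraction of decoy domains covered by gold
    # chance a gene outside the disease pathways still has a SNP in the
    # moderate-significance band (the band is mostly noise in real GWAS,
    # which is what the PSD filter is supposed to clean up)
    moderate_band_noise_rate: float = 0.4
    n_disease_pathways: int = 3
    n_snps_per_gene: int = 3
    n_interaction_edges: int = 320
    allow_multi_planting: bool = True   # permit > 1 planted domain per pathway

    def __post_init__(self) -> None:
        for name in (
            "planted_fraction",
            "carrier_rate",
            "background_rate",
            "gwas_signal_strength",
            "second_pathway_rate",
            "gold_decoy_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_proteins", "n_domains", "n_pathways", "region_length_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_planted = round(self.planted_fraction * self.n_domains)
        if n_planted > self.n_pathways and not self.allow_multi_planting:
            raise ValueError(
                f"{n_planted} planted domains for {self.n_pathways} pathways: "
                "set allow_multi_planting=True for more than one per pathway"
            )


@dataclass
class SyntheticUniverse:
    """All generated tables plus the ground truth behind them."""

    config: UniverseConfig
    annotations: pd.DataFrame            # protein_id, domain_id
    pathways: dict[str, set[str]]        # pathway_id -> member protein/gene ids
    gold_domain_pathway: GoldStandardDomainPathwayPairs
    genes: pd.DataFrame                  # gene_id, chrom, start, end, strand (1-based incl.)
    regions: pd.DataFrame                # chrom, start, end, domain_id (0-based half-open)
    variants: pd.DataFrame               # chrom, pos (1-based), class_label
    interaction_edges: list[tuple[str, str]]
    gwas: pd.DataFrame                   # snp_id, chrom, pos, p
    seed_genes: set[str]
    validation_genes: set[str]
    truth: dict[str, str] = field(default_factory=dict)  # domain -> planted-PSD | decoy
    planted_pathway: dict[str, str] = field(default_factory=dict)  # planted domain -> pathway
    disease_pathways: set[str] = field(default_factory=set)

    @property
    def planted_domains(self) -> set[str]:
        return {d for d, t in self.truth.items() if t == "planted-PSD"}

    def gene_domains(self) -> dict[str, set[str]]:
        """gene_id -> set of annotated domains (genes and proteins coincide)."""
        return {
            g: set(grp["domain_id"])
            for g, grp in self.annotations.groupby("protein_id")
        }

    def region_set(self, labels: dict[str, str] | pd.Series) -> DomainRegionSet:
        """Label the domain regions (e.g. with classified PSD/NSD calls) and
        build the interval structure for variant counting.  Regions of
        unlabeled domains are dropped."""
        lab = dict(labels) if not isinstance(labels, dict) else labels
        reg = self.regions.copy()
        reg["label"] = reg["domain_id"].map(lab)
        reg = reg.dropna(subset=["label"]).reset_index(drop=True)
        return DomainRegionSet(regions=reg)

    def truth_region_set(self) -> DomainRegionSet:
        """Regions labeled by ground truth (planted -> PSD, decoy -> NSD)."""
        return self.region_set(
            {d: ("PSD" if t == "planted-PSD" else "NSD") for d, t in self.truth.items()}
        )

    def write(self, out_dir: str | Path) -> None:
        """Write every table in the formats the pipeline consumes."""
        from . import io as psio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        psio.write_annotations(self.annotations, out / "annotations.tsv")
        psio.write_gmt(self.pathways, out / "pathways.gmt")
        psio.write_domain_pathway_gold(self.gold_domain_pathway, out / "gold_domain_pathway.tsv")
        psio.write_genes_bed(self.genes, out / "genes.bed")
        truth_labels = {
            d: ("PSD" if t == "planted-PSD" else "NSD") for d, t in self.truth.items()
        }
        reg = self.regions.copy()
        reg["label"] = reg["domain_id"].map(truth_labels)
        psio.write_regions_bed(reg, out / "domain_regions.bed")
        psio.write_variants(self.variants, out / "variants.tsv")
        psio.write_edges(self.interaction_edges, out / "interaction_edges.tsv")
        psio.write_gwas(self.gwas, out / "gwas.tsv")
        (out / "seed_genes.txt").write_text("".join(f"{g}\n" for g in sorted(self.seed_genes)))
        (out / "validation_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(self.validation_genes))
        )
        truth = pd.DataFrame(
            sorted(self.truth.items()), columns=["domain_id", "truth"]
        )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_universe(config: UniverseConfig | None = None) -> SyntheticUniverse:
    """Generate the full synthetic universe from a config (defaults above)."""
    cfg = config or UniverseConfig()
    rng = np.random.default_rng(cfg.seed)

    proteins = _ids("P", cfg.n_proteins)
    domains = _ids("D", cfg.n_domains)
    pathway_ids = _ids("PWY", cfg.n_pathways)

    # --- pathway membership: balanced primary assignment, occasional second ---
    shuffled = rng.permutation(cfg.n_proteins)
    pathways: dict[str, set[str]] = {pid: set() for pid in pathway_ids}
    for slot, pi in enumerate(shuffled):
        pathways[pathway_ids[slot % cfg.n_pathways]].add(proteins[pi])
    second_mask = rng.random(cfg.n_proteins) < cfg.second_pathway_rate
    second_choice = rng.integers(0, cfg.n_pathways, size=cfg.n_proteins)
    for prot, flag, k in zip(proteins, second_mask, second_choice):
        if flag:
            pathways[pathway_ids[k]].add(prot)

    # --- planted domains, round-robin over pathways ---
    n_planted = round(cfg.planted_fraction * cfg.n_domains)
    planted = domains[:n_planted]
    truth = {d: ("planted-PSD" if d in set(planted) else "decoy") for d in domains}
    planted_pathway = {
        d: pathway_ids[i % cfg.n_pathways] for i, d in enumerate(planted)
    }

    # --- occurrence ---
    # planted domains occur at background_rate everywhere (carriers on
    # top); decoy domains are generic and more prevalent, with rates
    # log-uniform between the multiplier bounds so domain occurrence is
    # heavy-tailed and planted domains are the rare ones
    lo, hi = cfg.decoy_prevalence_multiplier
    mult = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_domains))
    rate = np.full(cfg.n_domains, cfg.background_rate)
    planted_set = set(planted)
    decoy_mask = np.array([d not in planted_set for d in domains])
    rate[decoy_mask] = np.minimum(cfg.background_rate * mult[decoy_mask], 0.9)
    occ = rng.random((cfg.n_proteins, cfg.n_domains)) < rate[None, :]
    prot_index = {p: i for i, p in enumerate(proteins)}
    for j, d in enumerate(domains):
        if truth[d] != "planted-PSD":
            continue
        members = sorted(pathways[planted_pathway[d]])
        carry = rng.random(len(members)) < cfg.carrier_rate
        for prot, c in zip(members, carry):
            if c:
                occ[prot_index[prot], j] = True
    rows = [
        (proteins[i], domains[j]) for i, j in zip(*np.nonzero(occ))
    ]
    annotations = pd.DataFrame(rows, columns=["protein_id", "domain_id"]).sort_values(
        ["protein_id", "domain_id"]
    ).reset_index(drop=True)

    # --- gold domain-pathway standard: planted pairs plus decoy negatives ---
    decoys = [d for d in domains if truth[d] == "decoy"]
    n_gold_decoys = round(cfg.gold_decoy_fraction * len(decoys))
    gold_decoys = list(rng.choice(decoys, size=n_gold_decoys, replace=False)) if n_gold_decoys else []
    positives = frozenset((d, planted_pathway[d]) for d in planted)
    gold_domains = sorted(set(planted) | set(gold_decoys))
    negatives = frozenset(
        (d, f) for d in gold_domains for f in pathway_ids
    ) - positives
    gold = GoldStandardDomainPathwayPairs(positives=positives, negatives=frozenset(negatives))

    # --- genome: fixed-length genes on one chromosome, regions nested inside ---
    genes = pd.DataFrame(
        {
            "gene_id": proteins,
            "chrom": CHROM,
            "start": [i * GENE_SPAN + 1 for i in range(cfg.n_proteins)],
            "end": [i * GENE_SPAN + GENE_LENGTH for i in range(cfg.n_proteins)],
            "strand": "+",
        }
    )
    max_slots = GENE_LENGTH // cfg.region_length_nt
    region_rows = []
    for prot, grp in annotations.groupby("protein_id"):
        g0 = int(genes.loc[genes["gene_id"] == prot, "start"].iloc[0]) - 1  # 0-based
        for slot, dom in enumerate(sorted(grp["domain_id"])):
            if slot >= max_slots:
                break
            start = g0 + slot * cfg.region_length_nt
            region_rows.append((CHROM, start, start + cfg.region_length_nt, dom))
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "domain_id"])

    # --- variants: pathogenic enriched in planted regions, neutral uniform ---
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    planted_region = regions["domain_id"].isin(set(planted)).to_numpy()
    w_path = lengths * np.where(planted_region, cfg.variant_enrichment_factor, 1.0)
    w_neut = lengths
    variant_rows = []
    for cls, w in (("pathogenic", w_path), ("neutral", w_neut)):
        idx = rng.choice(len(regions), size=cfg.n_variants, p=w / w.sum())
        offsets = rng.integers(0, lengths[idx].astype(int))
        pos = regions["start"].to_numpy()[idx] + offsets + 1  # 1-based
        variant_rows.extend((CHROM, int(p), cls) for p in pos)
    variants = pd.DataFrame(variant_rows, columns=["chrom", "pos", "class_label"])

    # --- domain interaction edges with a heavy-tailed degree profile ---
    order = rng.permutation(cfg.n_domains)
    attach = 1.0 / (np.arange(cfg.n_domains) + 1.0) ** 0.8
    attach = attach[np.argsort(order)]  # shuffle which domains are hubs
    attach /= attach.sum()
    edge_set: set[tuple[str, str]] = set()
    draws = rng.choice(cfg.n_domains, size=(cfg.n_interaction_edges * 3, 2), p=attach)
    for a, b in draws:
        if a == b:
            continue
        da, db = domains[a], domains[b]
        edge_set.add((min(da, db), max(da, db)))
        if len(edge_set) >= cfg.n_interaction_edges:
            break
    interaction_edges = sorted(edge_set)

    # --- disease structure and GWAS summary ---
    disease_pathways = set(pathway_ids[: cfg.n_disease_pathways])
    disease_members = sorted(set().union(*(pathways[f] for f in disease_pathways)))
    perm = rng.permutation(len(disease_members))
    half = len(disease_members) // 2
    seed_genes = {disease_members[i] for i in perm[:half]}
    validation_genes = {disease_members[i] for i in perm[half:]}

    gwas_rows = []
    snp_counter = 0
    member_set = set(disease_members)
    for gene_id, start, end in genes[["gene_id", "start", "end"]].itertuples(index=False):
        n_snps = cfg.n_snps_per_gene
        pos = rng.integers(start - 5000, end + 5000, size=n_snps)
        pvals = rng.random(n_snps)
        in_band_rate = (
            cfg.gwas_signal_strength
            if gene_id in member_set
            else cfg.moderate_band_noise_rate
        )
        if rng.random() < in_band_rate:
            # one moderately significant SNP: log-uniform in (1e-6, 1e-3.01]
            pvals[0] = 10.0 ** rng.uniform(-6.0, -3.01)
        for p_, pv in zip(pos, pvals):
            snp_counter += 1
            gwas_rows.append((f"rs{snp_counter:06d}", CHROM, int(p_), float(pv)))
    gwas = pd.DataFrame(gwas_rows, columns=["snp_id", "chrom", "pos", "p"])

    return SyntheticUniverse(
        config=cfg,
        annotations=annotations,
        pathways=pathways,
        gold_domain_pathway=gold,
        genes=genes,
        regions=regions,
        variants=variants,
        interaction_edges=interaction_edges,
        gwas=gwas,
        seed_genes=seed_genes,
        validation_genes=validation_genes,
        truth=truth,
        planted_pathway=planted_pathway,
        disease_pathways=disease_pathways,
    )


def generate_worked_example(seed: int = 7) -> SyntheticUniverse:
    """A deliberately tiny universe (8 proteins, 6 domains, 3 pathways) on
    which every score can be checked against a brute-force transcription of
    the definitions."""
    cfg = UniverseConfig(
        n_proteins=8,
        n_domains=6,
        n_pathways=3,
        planted_fraction=0.5,
        carrier_rate=1.0,
        background_rate=0.15,
        n_variants=40,
        n_interaction_edges=8,
        n_disease_pathways=1,
        seed=seed,
    )
    return generate_universe(cfg)
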