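"""GWAS candidate-gene prioritization with disease-associated PSDs.

GWASs leave a large pool of SNPs with moderate significance
(1e-7 < p <= 1e-3) that single studies cannot call.  This module rescues
candidates from that pool using pathway-specific domains: pathways
significantly overlapping a seed set of known disease genes (one-sided
Fisher's exact test within a gene universe, pathways with >= 5 members
only) mark their significantly associated PSDs as disease PSDs, and a
moderately significant gene is selected when it carries at least
``min_count`` (default 3) such domains — the GWAS∩PSD set.  Precision is
evaluated against an independent validation gene set, disjoint from the
seed genes.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from scipy import stats

from .specificity import SpecificityResult

__all__ = [
    "assign_snps_to_genes",
    "select_moderate_genes",
    "derive_disease_psds",
    "select_candidates",
    "evaluate_precision",
]


def assign_snps_to_genes(
    gwas: pd.DataFrame,
    genes: pd.DataFrame,
    window_nt: int = 10_000,
) -> dict[str, pd.DataFrame]:
    """Assign each SNP to every gene within ``window_nt`` of its body.

    ``gwas`` has columns snp_id, chrom, pos (1-based), p; ``genes`` has
    gene_id, chrom, start, end (1-based inclusive).  A SNP maps to a gene
    when pos is in [start - window, end + window], bounds inclusive; a SNP
    may map to several genes.  Returns gene_id -> DataFrame of its SNPs.
    """
    out: dict[str, pd.DataFrame] = {}
    for chrom, gw in gwas.groupby("chrom"):
        gn = genes[genes["chrom"] == chrom]
        if len(gn) == 0:
            continue
        pos = gw["pos"].to_numpy()
        for gene_id, start, end in gn[["gene_id", "start", "end"]].itertuples(
            index=False
        ):
            mask = (pos >= start - window_nt) & (pos <= end + window_nt)
            if mask.any():
                out[gene_id] = pd.concat([out[gene_id], gw[mask]]) if gene_id in out else gw[mask]
    return out


def select_moderate_genes(
    assignments: Mapping[str, pd.DataFrame],
    p_low: float = 1e-7,
    p_high: float = 1e-3,
) -> set[str]:
    """Genes with at least one assigned SNP of moderate significance,
    p_low < p <= p_high (lower bound strict, upper bound inclusive)."""
    return {
        gene
        for gene, snps in assignments.items()
        if ((snps["p"] > p_low) & (snps["p"] <= p_high)).any()
    }


def derive_disease_psds(
    seed_genes: set[str],
    pathways: Mapping[str, set[str]],
    specificity: SpecificityResult,
    universe_size: int,
    sig: float = 0.01,
    min_pathway_size: int = 5,
) -> tuple[set[str], set[str]]:
    """Disease-associated PSDs via seed-gene / pathway-gene overlap.

    A pathway is disease-associated iff it has >= ``min_pathway_size``
    members and its overlap with the seed genes is significant (one-sided
    hypergeometric / Fisher p < ``sig``) within a universe of
    ``universe_size`` genes.  The disease PSD set is the union of PSDs
    whose significant (top-k) associations involve any disease-associated
    pathway.  Returns (disease_psds, disease_pathways).
    """
    if not seed_genes:
        raise ValueError("empty seed gene set")
    disease_pathways: set[str] = set()
    n_seed = len(seed_genes)
    for pid, members in pathways.items():
        members = set(members)
        if len(members) < min_pathway_size:
            continue
        overlap = len(members & seed_genes)
        if overlap == 0:
            continue
        # P(X >= overlap), X ~ Hypergeom(universe, n_seed, |pathway|)
        p = float(
            stats.hypergeom.sf(overlap - 1, universe_size, n_seed, len(members))
        )
        if p < sig:
            disease_pathways.add(pid)
    sig_assoc = specificity.significant_associations()
    psd = specificity.psd_domains
    disease_psds = set(
        sig_assoc.loc[
            sig_assoc["pathway_id"].isin(disease_pathways)
            & sig_assoc["domain_id"].isin(psd),
            "domain_id",
        ]
    )
    return disease_psds, disease_pathways


def select_candidates(
    moderate_genes: set[str],
    gene_domains: Mapping[str, set[str]],
    disease_psds: set[str],
    min_count: int = 3,
    gene_min_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Build the prioritization table over the moderate-significance genes.

    A gene is selected iff it carries >= ``min_count`` disease PSDs.
    Returns columns gene_id, min_p, n_disease_psds, selected, sorted by
    (n_disease_psds desc, min_p asc, gene_id).
    """
    rows = []
    for gene in sorted(moderate_genes):
        n = len(set(gene_domains.get(gene, set())) & disease_psds)
        rows.append(
            {
                "gene_id": gene,
                "min_p": float(gene_min_p[gene]) if gene_min_p else float("nan"),
                "n_disease_psds": n,
                "selected": n >= min_count,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "min_p", "n_disease_psds", "selected"]
    )
    return table.sort_values(
        ["n_disease_psds", "min_p", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def evaluate_precision(
    table: pd.DataFrame,
    validation: set[str],
    universe_size: int,
) -> tuple[float, float]:
    """Precision of the selected genes against an independent validation set,
    with the random-expectation baseline |validation| / universe_size."""
    selected = set(table.loc[table["selected"], "gene_id"])
    if not selected:
        raise ValueError("no gene selected; precision undefined")
    precision = len(selected & validation) / len(selected)
    baseline = len(validation) / universe_size
    return precision, baseline
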