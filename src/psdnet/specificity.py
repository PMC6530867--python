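"""Pathway specificity scoring: PPA, DPA, Gini index, PS, and PSD/NSD labels.

The chain of scores:

* ``s_i(f)`` — sum of positive-LLS edge weights from protein *i* to the
  member proteins of pathway *f*.
* ``PPA_i(f) = 1 - (s_min(f) / s_i(f)) ** alpha(f)`` — one minus the Pareto
  tail probability of that sum.  The positive sums for a pathway are
  modelled as Pareto with scale ``s_min`` (the minimum observed positive
  sum) and maximum-likelihood shape ``alpha = 1 + n / sum(ln(s_i/s_min))``,
  lower-clamped at 1 because very small pathways otherwise yield shapes
  too shallow to de-skew the sums.
* ``DPA_j(f)`` — mean PPA over the carrier set of domain *j* (the proteins
  containing it that appear in the network).
* ``GI_j = 1 - sum_f (DPA_j(f) / sum_f DPA_j(f))**2`` — impurity of the
  domain's DPA distribution across pathways; 0 when a single pathway holds
  all the mass.
* ``PS_j(f) = (1 - GI_j) * DPA_j(f)`` — the ranking statistic.

Domains are classified as pathway-specific (PSD) when they appear in the
top-k PS-ranked associations, where k is the largest rank cutoff at which
the top-k set is significantly enriched (one-sided Fisher's exact test)
for gold-standard domain-pathway pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copathway import CoPathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandardDomainPathwayPairs",
    "SpecificityResult",
    "pathway_link_sum",
    "fit_pareto_shape",
    "compute_ppa",
    "compute_dpa",
    "compute_gini",
    "compute_ps",
    "classify_psd",
]


@dataclass(frozen=True)
class GoldStandardDomainPathwayPairs:
    """Curated domain-pathway pairs: positives are known associations,
    negatives pair a gold domain with a gold pathway it is not annotated to."""

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("gold positives and negatives overlap")


def pathway_link_sum(
    network: CoPathwayNetwork, protein: str, members: set[str]
) -> float:
    """Sum of LLS over the protein's network edges into ``members``.

    The protein's own membership contributes nothing (no self-edges).
    Returns 0.0 when no neighbor is a member.
    """
    neigh = network.adjacency.get(protein, {})
    return float(sum(lls for other, lls in neigh.items() if other in members))


def fit_pareto_shape(sums: Sequence[float]) -> tuple[float, float]:
    """Fit (s_min, alpha) of a Pareto model to strictly positive link sums.

    ``s_min`` is the minimum of the sample; ``alpha`` is the maximum-
    likelihood shape ``1 + n / sum(ln(s_i / s_min))``, lower-clamped at 1.
    When all sums are equal the log-spread is zero and alpha is returned
    as ``math.inf`` (the tail probability at s = s_min is then 1, i.e.
    PPA = 0, which is the correct continuity limit).
    """
    s = np.asarray(list(sums), dtype=float)
    if s.size == 0:
        raise ValueError("pathway has no connected proteins")
    if (s <= 0).any():
        raise ValueError("link sums must be strictly positive")
    s_min = float(s.min())
    # difference of logs: s / s_min can overflow for extreme spreads
    log_spread = float((np.log(s) - np.log(s_min)).sum())
    if log_spread == 0.0:
        return s_min, math.inf
    alpha = 1.0 + s.size / log_spread
    return s_min, max(1.0, alpha)


def _pareto_ppa(s: float, s_min: float, alpha: float) -> float:
    if s <= 0:
        return 0.0
    if math.isinf(alpha):
        # all positive sums equal s_min; tail prob is 1 at the boundary
        return 0.0 if s <= s_min else 1.0
    return 1.0 - (s_min / s) ** alpha


def compute_ppa(
    network: CoPathwayNetwork,
    pathways: Mapping[str, set[str]],
    exclude_self_pathway: bool = False,
) -> pd.DataFrame:
    """Protein-pathway association scores for every network protein.

    Returns a DataFrame indexed by protein (lexicographic), one column per
    pathway.  Proteins with a zero link sum toward a pathway get PPA 0;
    the Pareto fit for each pathway uses the positive sums only.  Pathways
    with no connected protein produce an all-zero column and a warning.

    With ``exclude_self_pathway`` the protein's own pathway membership is
    removed from the member set before summing (a guard against
    self-reinforcement; off by default).
    """
    proteins = sorted(network.proteins)
    ppa = pd.DataFrame(
        0.0, index=pd.Index(proteins, name="protein_id"), columns=sorted(pathways)
    )
    ppa.columns.name = "pathway_id"
    for pid in ppa.columns:
        members = set(pathways[pid])
        sums = np.array(
            [
                pathway_link_sum(
                    network, prot, members - {prot} if exclude_self_pathway else members
                )
                for prot in proteins
            ]
        )
        positive = sums[sums > 0]
        if positive.size == 0:
            warnings.warn(f"pathway {pid!r} has no connected protein; PPA column is 0")
            continue
        s_min, alpha = fit_pareto_shape(positive)
        ppa[pid] = [_pareto_ppa(s, s_min, alpha) for s in sums]
    return ppa


def compute_dpa(ppa: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Domain-pathway association: mean PPA over each domain's carrier set.

    The carrier set K of domain j holds the proteins with c_ij = 1 that
    are present in the PPA index (i.e. in the network).  Domains with an
    empty carrier set are excluded from the result and logged.
    """
    scored = matrix.index.intersection(ppa.index)
    sub = matrix.loc[scored]
    carriers = sub.sum(axis=0)
    kept = carriers[carriers > 0].index
    dropped = carriers[carriers == 0].index
    if len(dropped):
        logger.info(
            "excluding %d domains with no carrier in the network", len(dropped)
        )
    # DPA = (C^T @ PPA) / |K|, restricted to carried domains
    C = sub[kept].to_numpy(dtype=float)
    vals = C.T @ ppa.loc[scored].to_numpy(dtype=float)
    vals /= carriers[kept].to_numpy(dtype=float)[:, None]
    dpa = pd.DataFrame(vals, index=pd.Index(kept, name="domain_id"), columns=ppa.columns)
    return dpa


def compute_gini(dpa_row: pd.Series | np.ndarray) -> float:
    """Gini impurity of a domain's DPA distribution across pathways.

    0 when a single pathway carries all the DPA mass; approaches
    1 - 1/F when the mass is spread evenly over F pathways.  An all-zero
    row returns NaN (handled by :func:`compute_ps`, which maps it to PS 0).
    """
    v = np.asarray(dpa_row, dtype=float)
    total = v.sum()
    if total == 0:
        return float("nan")
    shares = v / total
    return float(1.0 - (shares**2).sum())


def compute_ps(dpa: pd.DataFrame) -> pd.DataFrame:
    """Build the long-form association table with DPA, Gini and PS.

    Returns one row per (domain, pathway) with columns ``domain_id``,
    ``pathway_id``, ``dpa``, ``gini``, ``ps`` and ``rank`` (1-based, PS
    descending, ties broken by identifiers for determinism).  Domains with
    an all-zero DPA row get PS 0 for every pathway.
    """
    gini = dpa.apply(compute_gini, axis=1)
    purity = (1.0 - gini).fillna(0.0)  # all-zero rows -> PS 0 regardless
    ps = dpa.mul(purity, axis=0)
    table = (
        ps.stack()
        .rename("ps")
        .reset_index()
        .rename(columns={"level_0": "domain_id", "level_1": "pathway_id"})
    )
    table["dpa"] = dpa.stack().to_numpy()
    table["gini"] = gini.reindex(table["domain_id"]).to_numpy()
    table = table.sort_values(
        ["ps", "domain_id", "pathway_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["domain_id", "pathway_id", "dpa", "gini", "ps", "rank"]]


@dataclass
class SpecificityResult:
    """Association table with PSD/NSD labels and the chosen cutoff."""

    table: pd.DataFrame  # domain_id, pathway_id, dpa, gini, ps, rank, label
    domain_labels: pd.Series  # domain_id -> "PSD" | "NSD"
    chosen_rank: int  # 0 when no cutoff reached significance
    chosen_ps_threshold: float  # NaN when no cutoff reached significance

    @property
    def psd_domains(self) -> set[str]:
        return set(self.domain_labels.index[self.domain_labels == "PSD"])

    def significant_associations(self) -> pd.DataFrame:
        """The top-k associations that define the PSD set."""
        return self.table[self.table["rank"] <= self.chosen_rank]


def _fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher's exact p for the 2x2 table
    [[top&pos, top&neg], [below&pos, below&neg]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def classify_psd(
    table: pd.DataFrame,
    gold: GoldStandardDomainPathwayPairs,
    significance: float = 0.01,
    rank_grid_step: int = 1000,
) -> SpecificityResult:
    """Label domains PSD/NSD via a rank-cutoff scan against gold pairs.

    Associations are walked in PS-rank order in consecutive segments of
    ``rank_grid_step`` (the last segment absorbs the remainder).  Each
    segment's overlap with the gold standard is tested by a one-sided
    Fisher's exact test contrasting (in-segment vs outside) x
    (gold-positive vs gold-negative), computed over the assessable
    associations only — those present in the gold positives or negatives.
    The chosen cutoff k is the end of the last contiguous significant
    segment from the top (high-PS segments are gold-enriched; the first
    segment whose overlap is no longer significant ends the PSD region).
    Associations tied in PS with the k-th are pulled into the top set.
    Domains appearing in at least one top-k association are PSD, all
    other scored domains NSD.
    """
    if not gold.positives or not gold.negatives:
        raise ValueError("gold standard needs positives and negatives")
    tab = table.sort_values("rank").reset_index(drop=True)
    keys = list(zip(tab["domain_id"], tab["pathway_id"]))
    is_pos = np.fromiter((k in gold.positives for k in keys), bool, len(keys))
    is_neg = np.fromiter((k in gold.negatives for k in keys), bool, len(keys))
    tot_pos, tot_neg = int(is_pos.sum()), int(is_neg.sum())
    if tot_pos == 0 or tot_neg == 0:
        raise ValueError("no assessable gold positives/negatives in the table")

    n = len(tab)
    bounds = list(range(rank_grid_step, n + 1, rank_grid_step))
    if not bounds or bounds[-1] < n:
        bounds.append(n)
    chosen_k = 0
    lo = 0
    for hi in bounds:
        a = int(is_pos[lo:hi].sum())
        b = int(is_neg[lo:hi].sum())
        p = _fisher_enrichment_p(a, b, tot_pos - a, tot_neg - b)
        if p > significance:
            break
        chosen_k = hi
        lo = hi

    out = tab.copy()
    if chosen_k == 0:
        warnings.warn("no rank cutoff reached significance; all domains labeled NSD")
        threshold = float("nan")
        psd: set[str] = set()
    else:
        threshold = float(out.loc[chosen_k - 1, "ps"])
        # pull PS ties at the boundary into the top set
        while chosen_k < n and out.loc[chosen_k, "ps"] == threshold:
            chosen_k += 1
        psd = set(out.loc[: chosen_k - 1, "domain_id"])
    out["label"] = np.where(out["domain_id"].isin(psd), "PSD", "NSD")
    domain_labels = (
        out[["domain_id", "label"]]
        .drop_duplicates()
        .set_index("domain_id")["label"]
        .sort_index()
    )
    return SpecificityResult(
        table=out,
        domain_labels=domain_labels,
        chosen_rank=chosen_k,
        chosen_ps_threshold=threshold,
    )
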