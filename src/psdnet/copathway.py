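"""Co-pathway protein network: weighted mutual information and LLS calibration.

Two proteins that share rare domains are likely to act in the same
biological pathway.  This module scores every unordered protein pair by the
weighted mutual information (WMI) of their Boolean domain profiles, where
the probability measure over domains is given by the rarity weights of
:mod:`psdnet.profiles`:

    p_w(X = t) = sum of omega_j over domains j with c_Xj = t, / sum of all omega_j

    I_w(X, Y) = H_w(X) + H_w(Y) - H_w(X, Y)

with entropies in nats.  WMI ranks are then calibrated into log-likelihood
scores (LLS) against gold-standard co-annotated protein pairs: pairs are
walked in descending WMI order in consecutive bins, and each bin's LLS is
the log posterior-to-prior odds of being a gold positive,

    LLS = ln[ (P(L|E) / P(~L|E)) / (P(L) / P(~L)) ],

estimated from the gold-standard members of the bin.  Edges with positive
LLS form the co-pathway network used by :mod:`psdnet.specificity`.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandardProteinPairs",
    "CoPathwayNetwork",
    "weighted_entropy",
    "weighted_joint_entropy",
    "weighted_mutual_information",
    "score_all_pairs",
    "build_gold_standard_pairs",
    "calibrate_lls",
    "filter_positive_lls",
]


def _plogp(p: np.ndarray) -> np.ndarray:
    # 0 * log 0 := 0
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def weighted_entropy(profile: np.ndarray, weights: np.ndarray) -> float:
    """Weighted entropy H_w(X) of a Boolean profile, in nats.

    The two-point distribution puts mass ``sum(weights[profile == 1]) / sum(weights)``
    on 1 and the complement on 0.  Bounded by ln 2.
    """
    profile = np.asarray(profile, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p1 = float(weights[profile > 0].sum() / weights.sum())
    p = np.array([1.0 - p1, p1])
    return float(-_plogp(p).sum())


def weighted_joint_entropy(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted joint entropy H_w(X, Y) over the four joint states 00/01/10/11."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    m11 = weights[x & y].sum() / total
    m10 = weights[x & ~y].sum() / total
    m01 = weights[~x & y].sum() / total
    m00 = weights[~x & ~y].sum() / total
    p = np.array([m00, m01, m10, m11])
    return float(-_plogp(p).sum())


def weighted_mutual_information(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> float:
    """I_w(X, Y) = H_w(X) + H_w(Y) - H_w(X, Y); symmetric and non-negative."""
    return (
        weighted_entropy(x, weights)
        + weighted_entropy(y, weights)
        - weighted_joint_entropy(x, y, weights)
    )


def _wmi_matrix(matrix: pd.DataFrame, weights: pd.Series) -> np.ndarray:
    """All-pairs WMI as a dense symmetric array (vectorised).

    For proteins stacked in C (n x m) with weight vector w, the joint mass
    on state 11 for every pair is (C * w) @ C.T / sum(w); the remaining
    three joint masses follow from the marginals, so the full n x n WMI
    matrix needs a single matrix product.
    """
    C = matrix.to_numpy(dtype=float)
    w = weights.reindex(matrix.columns).to_numpy(dtype=float)
    total = w.sum()
    p1 = (C @ w) / total                      # per-protein mass on 1
    M11 = (C * w) @ C.T / total               # pairwise mass on (1, 1)
    M10 = p1[:, None] - M11
    M01 = p1[None, :] - M11
    M00 = 1.0 - M11 - M10 - M01
    H_joint = -(_plogp(M11) + _plogp(M10) + _plogp(M01) + _plogp(M00))
    h = -(_plogp(p1) + _plogp(1.0 - p1))
    wmi = h[:, None] + h[None, :] - H_joint
    # numerical noise can push exact zeros slightly negative
    np.clip(wmi, 0.0, None, out=wmi)
    return wmi


def score_all_pairs(matrix: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Score every unordered protein pair by WMI.

    Returns a DataFrame with columns ``protein_a``, ``protein_b``, ``wmi``
    containing exactly n(n-1)/2 rows sorted by descending WMI, ties broken
    lexicographically by (protein_a, protein_b) so the ranking (and hence
    the LLS binning) is deterministic.  ``protein_a < protein_b`` in every
    row.
    """
    n = len(matrix.index)
    if n < 2:
        raise ValueError("need at least two proteins to score pairs")
    wmi = _wmi_matrix(matrix, weights)
    ia, ib = np.triu_indices(n, k=1)
    proteins = matrix.index.to_numpy()
    pairs = pd.DataFrame(
        {
            "protein_a": proteins[ia],
            "protein_b": proteins[ib],
            "wmi": wmi[ia, ib],
        }
    )
    pairs = pairs.sort_values(
        ["wmi", "protein_a", "protein_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return pairs


@dataclass(frozen=True)
class GoldStandardProteinPairs:
    """Gold-standard co-pathway protein pairs (positives) and non-co-pathway
    pairs (negatives); both stored as frozensets of sorted 2-tuples."""

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("gold positives and negatives overlap")


def build_gold_standard_pairs(
    pathways: Mapping[str, set[str]], proteins: Iterable[str]
) -> GoldStandardProteinPairs:
    """Derive gold-standard protein pairs from pathway co-annotation.

    Positives are pairs sharing at least one pathway; negatives are pairs
    in which both proteins are annotated (each to >= 1 pathway) but share
    none.  Proteins without any pathway annotation contribute to neither
    set.  Pathway sets are restricted to ``proteins`` first.
    """
    universe = set(proteins)
    membership: dict[str, set[str]] = {}
    for pid, members in pathways.items():
        for prot in members & universe if isinstance(members, set) else set(members) & universe:
            membership.setdefault(prot, set()).add(pid)
    if not membership:
        raise ValueError("no protein is annotated to any pathway")
    annotated = sorted(membership)
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(annotated, 2):
        if membership[a] & membership[b]:
            positives.add((a, b))
        else:
            negatives.add((a, b))
    return GoldStandardProteinPairs(frozenset(positives), frozenset(negatives))


@dataclass
class CoPathwayNetwork:
    """Protein network with per-edge log-likelihood scores (nats)."""

    edges: pd.DataFrame  # columns protein_a, protein_b, lls
    _adjacency: dict[str, dict[str, float]] = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def adjacency(self) -> dict[str, dict[str, float]]:
        """Symmetric neighbor -> lls maps, built lazily."""
        if self._adjacency is None:
            adj: dict[str, dict[str, float]] = {}
            for a, b, lls in self.edges[["protein_a", "protein_b", "lls"]].itertuples(
                index=False
            ):
                adj.setdefault(a, {})[b] = float(lls)
                adj.setdefault(b, {})[a] = float(lls)
            self._adjacency = adj
        return self._adjacency

    @property
    def proteins(self) -> set[str]:
        return set(self.adjacency)


def calibrate_lls(
    pairs: pd.DataFrame,
    gold: GoldStandardProteinPairs,
    bin_size: int = 1000,
) -> CoPathwayNetwork:
    """Assign a log-likelihood score to every pair from its WMI-rank bin.

    ``pairs`` must be sorted by descending WMI (the output of
    :func:`score_all_pairs`).  Consecutive bins of ``bin_size`` pairs are
    formed; a bin's LLS is computed from its gold-standard member counts
    against the prior odds over all gold pairs.  Bins whose gold members
    are all positive or all negative are merged forward with the next bin
    until both counts are nonzero (equivalent to taking a larger bin); a
    deficient trailing bin merges backward into its predecessor.

    All pairs in a bin — gold members or not — receive the bin's LLS.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    n_pos_total = len(gold.positives)
    n_neg_total = len(gold.negatives)
    if n_pos_total == 0 or n_neg_total == 0:
        raise ValueError("degenerate prior: gold standard needs positives and negatives")
    prior_odds = n_pos_total / n_neg_total

    keys = list(zip(pairs["protein_a"], pairs["protein_b"]))
    is_pos = np.fromiter((k in gold.positives for k in keys), bool, len(keys))
    is_neg = np.fromiter((k in gold.negatives for k in keys), bool, len(keys))

    n = len(pairs)
    starts = list(range(0, n, bin_size))
    # group raw bins, merging forward while a group lacks positives or negatives
    groups: list[tuple[int, int, int, int]] = []  # (start, stop, n_pos, n_neg)
    i = 0
    while i < len(starts):
        start = starts[i]
        stop = min(start + bin_size, n)
        npos = int(is_pos[start:stop].sum())
        nneg = int(is_neg[start:stop].sum())
        i += 1
        while (npos == 0 or nneg == 0) and i < len(starts):
            nxt = min(starts[i] + bin_size, n)
            npos += int(is_pos[stop:nxt].sum())
            nneg += int(is_neg[stop:nxt].sum())
            stop = nxt
            i += 1
        groups.append((start, stop, npos, nneg))
    # trailing group still deficient (or a partial final bin): merge backward
    while len(groups) > 1 and (
        groups[-1][2] == 0 or groups[-1][3] == 0 or groups[-1][1] - groups[-1][0] < bin_size
    ):
        s1, e1, p1_, n1 = groups[-2]
        s2, e2, p2_, n2 = groups[-1]
        groups = groups[:-2] + [(s1, e2, p1_ + p2_, n1 + n2)]
    lls = np.empty(n, dtype=float)
    for start, stop, npos, nneg in groups:
        if npos == 0 or nneg == 0:
            # single remaining group with one-sided gold: no likelihood estimate
            raise ValueError(
                "cannot estimate LLS: gold members are one-sided even after merging"
            )
        lls[start:stop] = np.log((npos / nneg) / prior_odds)

    edges = pairs[["protein_a", "protein_b"]].copy()
    edges["lls"] = lls
    return CoPathwayNetwork(edges=edges)


def filter_positive_lls(network: CoPathwayNetwork) -> CoPathwayNetwork:
    """Keep only edges with strictly positive LLS; isolated proteins drop out
    of the adjacency automatically."""
    kept = network.edges[network.edges["lls"] > 0].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("no edges with positive LLS; returning an empty network")
    return CoPathwayNetwork(edges=kept)
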