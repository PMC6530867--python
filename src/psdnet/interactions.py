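"""PSD/NSD enrichment among interfacing domains by interaction connectivity.

Interfacing domains (IFDs) mediate physical domain-domain contacts in a
structurally resolved interaction network.  To ask whether pathway-specific
domains are over- or under-represented among IFDs of a given connectivity,
domains are grouped into bins of similar size along the degree axis (degree
distributions are heavy-tailed, so equal-width degree intervals would give
wildly uneven groups) and each bin is summarised by the log2 Domain Ratio

    log2[ (|PSD in bin| / |PSD total|) / (|NSD in bin| / |NSD total|) ],

positive when PSDs are enriched in that connectivity range.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "degree_map",
    "bin_domains_by_degree",
    "domain_ratio",
    "degree_bin_report",
]


def degree_map(edges: Sequence[tuple[str, str]]) -> dict[str, int]:
    """Number of distinct interaction partners per domain (self-loops and
    duplicate edges ignored)."""
    partners: dict[str, set[str]] = {}
    for a, b in edges:
        if a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return {d: len(p) for d, p in partners.items()}


def bin_domains_by_degree(
    degrees: Mapping[str, int], n_bins: int
) -> list[list[str]]:
    """Partition domains into ``n_bins`` contiguous degree groups of similar size.

    Domains are sorted by degree; ties (all domains of one degree) always
    land in the same bin, so realised bin sizes can differ by up to the
    largest tie block.  A greedy sweep closes each bin once it reaches the
    running target size for the remaining bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(degrees) < n_bins:
        raise ValueError("fewer domains than bins")
    distinct = sorted(set(degrees.values()))
    if n_bins > len(distinct):
        warnings.warn(
            f"only {len(distinct)} distinct degrees; returning {len(distinct)} bins"
        )
        n_bins = len(distinct)
    blocks = [
        sorted(d for d, k in degrees.items() if k == deg) for deg in distinct
    ]
    bins: list[list[str]] = []
    remaining = sum(len(b) for b in blocks)
    bi = 0
    for b_left in range(n_bins, 0, -1):
        current: list[str] = []
        # leave at least one block per remaining bin
        while bi < len(blocks) and (len(blocks) - bi) > (b_left - 1):
            target = remaining / b_left
            if current and len(current) + len(blocks[bi]) / 2 > target:
                break
            current.extend(blocks[bi])
            bi += 1
        bins.append(current)
        remaining -= len(current)
    return bins


def domain_ratio(
    psd_total: int, nsd_total: int, psd_in_group: int, nsd_in_group: int
) -> float:
    """log2 Domain Ratio of a bin; +inf when the bin has PSDs but no NSDs,
    -inf in the opposite case, NaN when it has neither."""
    if psd_total <= 0 or nsd_total <= 0:
        raise ValueError("totals must be positive")
    if psd_in_group == 0 and nsd_in_group == 0:
        return float("nan")
    if nsd_in_group == 0:
        return math.inf
    if psd_in_group == 0:
        return -math.inf
    ratio = (psd_in_group / psd_total) / (nsd_in_group / nsd_total)
    return math.log2(ratio)


def degree_bin_report(
    degrees: Mapping[str, int],
    labels: Mapping[str, str],
    n_bins: int,
    psd_total: int | None = None,
    nsd_total: int | None = None,
) -> pd.DataFrame:
    """Per-bin PSD/NSD counts and log2 Domain Ratio.

    ``labels`` maps domain_id -> "PSD"/"NSD"; domains without a label are
    skipped.  ``psd_total``/``nsd_total`` default to the labeled counts
    among the binned domains (pass genome-wide totals to normalise against
    the full domain universe instead).
    """
    labeled = {d: k for d, k in degrees.items() if labels.get(d) in ("PSD", "NSD")}
    bins = bin_domains_by_degree(labeled, n_bins)
    if psd_total is None:
        psd_total = sum(1 for d in labeled if labels[d] == "PSD")
    if nsd_total is None:
        nsd_total = sum(1 for d in labeled if labels[d] == "NSD")
    rows = []
    for members in bins:
        degs = [labeled[d] for d in members]
        n_psd = sum(1 for d in members if labels[d] == "PSD")
        n_nsd = len(members) - n_psd
        rows.append(
            {
                "degree_lo": min(degs),
                "degree_hi": max(degs),
                "n_psd": n_psd,
                "n_nsd": n_nsd,
                "log2_domain_ratio": domain_ratio(psd_total, nsd_total, n_psd, n_nsd),
            }
        )
    return pd.DataFrame(rows)
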