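"""Variant-density enrichment between PSD and NSD genomic regions.

For each variant class (pathogenic, neutral, edgetic, ...) and each domain
class (PSD/NSD) the variation rate is

    VR = variants in the class's regions / nucleotides in those regions,

the background rate BVR pools both domain classes, and the normalized
variation rate NVR = VR / BVR.  NVR > 1 means the variant class is denser
in that domain class than in domain regions overall.  Significance of the
PSD-NSD difference is an exact two-sided binomial test of the PSD variant
count among all in-domain variants against the null proportion given by
the PSD share of domain nucleotides.

Coordinate conventions: regions are BED-style (0-based, half-open);
variant positions are VCF-style (1-based).  Regions sharing a domain-class
label are merged before nucleotide counting, so overlapping annotations
are not double-counted and a variant counts at most once per label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "DomainRegionSet",
    "count_variants_in_regions",
    "compute_nvr",
    "nvr_difference_test",
]


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(iv):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class DomainRegionSet:
    """Genomic regions of annotated domains, each labeled PSD or NSD.

    ``regions`` has columns chrom, start, end, domain_id, label with
    0-based half-open coordinates.  Merged interval trees per
    (label, chrom) and per-label nucleotide totals are built on
    construction.
    """

    regions: pd.DataFrame
    trees: dict[tuple[str, str], IntervalTree] = field(init=False, repr=False)
    total_nt: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        bad = self.regions[self.regions["start"] >= self.regions["end"]]
        if len(bad):
            raise ValueError(
                f"malformed interval (start >= end) at input row {bad.index[0]}"
            )
        self.trees = {}
        self.total_nt = {}
        for (label, chrom), grp in self.regions.groupby(["label", "chrom"]):
            merged = _merge_intervals(list(zip(grp["start"], grp["end"])))
            tree = IntervalTree()
            for start, end in merged:
                tree[start:end] = label
            self.trees[(label, chrom)] = tree
            self.total_nt[label] = self.total_nt.get(label, 0) + sum(
                e - s for s, e in merged
            )

    @property
    def labels(self) -> list[str]:
        return sorted(self.total_nt)


def count_variants_in_regions(
    variants: pd.DataFrame, regions: DomainRegionSet
) -> pd.DataFrame:
    """Count variants falling in each (variant class, domain class) cell.

    ``variants`` has columns chrom, pos (1-based), class_label.  A variant
    at 1-based position p lies in region [start, end) iff
    start <= p - 1 < end.  A variant inside both a PSD and an NSD region
    counts once for each label.
    """
    classes = sorted(variants["class_label"].unique())
    counts = pd.DataFrame(0, index=classes, columns=regions.labels)
    counts.index.name = "class_label"
    for chrom, pos, cls in variants[["chrom", "pos", "class_label"]].itertuples(
        index=False
    ):
        for label in regions.labels:
            tree = regions.trees.get((label, chrom))
            if tree is not None and tree.overlaps_point(int(pos) - 1):
                counts.loc[cls, label] += 1
    return counts


def compute_nvr(counts: pd.DataFrame, total_nt: dict[str, int]) -> pd.DataFrame:
    """Per-class VR, BVR and NVR report.

    Returns one row per (class_label, region label) with columns
    ``variant_count``, ``nt_count``, ``vr``, ``bvr``, ``nvr``.  A class
    with zero variants overall has an undefined NVR, reported as NaN.
    """
    labels = sorted(total_nt)
    for lab in labels:
        if total_nt[lab] <= 0:
            raise ValueError(f"label {lab!r} has zero nucleotides")
    nt_all = sum(total_nt[lab] for lab in labels)
    rows = []
    for cls in counts.index:
        n_all = int(counts.loc[cls, labels].sum())
        bvr = n_all / nt_all
        for lab in labels:
            k = int(counts.loc[cls, lab])
            vr = k / total_nt[lab]
            nvr = vr / bvr if bvr > 0 else float("nan")
            rows.append(
                {
                    "class_label": cls,
                    "region_label": lab,
                    "variant_count": k,
                    "nt_count": total_nt[lab],
                    "vr": vr,
                    "bvr": bvr,
                    "nvr": nvr,
                }
            )
    return pd.DataFrame(rows)


def nvr_difference_test(
    counts: pd.DataFrame,
    total_nt: dict[str, int],
    class_label: str,
    test_label: str = "PSD",
    other_label: str = "NSD",
) -> float:
    """Exact two-sided binomial p for a PSD/NSD density difference.

    Conditions on the total in-domain variant count of the class: under
    the null of uniform density, the count in ``test_label`` regions is
    Binomial(n, nt_test / (nt_test + nt_other)).
    """
    k = int(counts.loc[class_label, test_label])
    n = k + int(counts.loc[class_label, other_label])
    if n == 0:
        raise ValueError(f"class {class_label!r} has no in-domain variants")
    p0 = total_nt[test_label] / (total_nt[test_label] + total_nt[other_label])
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
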