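"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: two-column annotation TSV, GMT gene sets, gold-pair TSV (optional
+/- third column), BED6 domain regions (0-based half-open, name field
``domain_id`` or ``domain_id|LABEL``), variant tables (three-column TSV or
a minimal VCF with a CLASS INFO tag), two-column interaction edges, GWAS
summary TSV, gene BED/TSV, and the matrix / weight / network / PS-table
TSVs produced by the pipeline itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .copathway import CoPathwayNetwork
from .specificity import GoldStandardDomainPathwayPairs

__all__ = [
    "read_annotations", "write_annotations",
    "read_gmt", "write_gmt",
    "read_matrix", "write_matrix",
    "read_weights", "write_weights",
    "read_network", "write_network",
    "read_domain_pathway_gold", "write_domain_pathway_gold",
    "read_regions_bed", "write_regions_bed",
    "read_variants", "write_variants",
    "read_edges", "write_edges",
    "read_gwas", "write_gwas",
    "read_genes_bed", "write_genes_bed",
    "read_gene_list",
    "read_ps_table", "write_ps_table",
]


def _has_header(first: str, markers: Sequence[str]) -> bool:
    token = first.split("\t")[0].strip().lower()
    return token in markers


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Two-column ``protein_id<TAB>domain_id`` TSV; a header line is
    auto-detected by its first token."""
    with open(path) as fh:
        first = fh.readline()
    header = 0 if _has_header(first, ("protein", "protein_id", "gene", "gene_id")) else None
    df = pd.read_csv(path, sep="\t", header=header, usecols=[0, 1], dtype=str)
    df.columns = ["protein_id", "domain_id"]
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations[["protein_id", "domain_id"]].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs id, description and >=1 gene: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{pid}\t{genes}\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "protein_id"
    df.columns.name = "domain_id"
    return df.astype("int8")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_weights(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.name = "omega"
    return s


def write_weights(weights: pd.Series, path: str | Path) -> None:
    weights.rename("omega").to_csv(path, sep="\t", index_label="domain_id")


def read_network(path: str | Path) -> CoPathwayNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return CoPathwayNetwork(edges=df[["protein_a", "protein_b", "lls"]])


def write_network(network: CoPathwayNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_domain_pathway_gold(path: str | Path) -> GoldStandardDomainPathwayPairs:
    """Two columns = all positives; an optional third ``+``/``-`` column
    splits positives from negatives."""
    pos: set[tuple[str, str]] = set()
    neg: set[tuple[str, str]] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.lower().startswith("domain"):
            continue
        parts = line.rstrip("\n").split("\t")
        pair = (parts[0], parts[1])
        if len(parts) >= 3 and parts[2].strip() == "-":
            neg.add(pair)
        else:
            pos.add(pair)
    return GoldStandardDomainPathwayPairs(frozenset(pos), frozenset(neg))


def write_domain_pathway_gold(
    gold: GoldStandardDomainPathwayPairs, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for d, f in sorted(gold.positives):
            fh.write(f"{d}\t{f}\t+\n")
        for d, f in sorted(gold.negatives):
            fh.write(f"{d}\t{f}\t-\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """BED with the domain id (optionally ``domain_id|LABEL``) in the name
    field; returns chrom, start, end, domain_id and, when present, label."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"BED line {lineno} needs >= 4 fields")
        name = parts[3]
        domain, _, label = name.partition("|")
        rows.append(
            {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
                "domain_id": domain,
                "label": label or None,
            }
        )
    df = pd.DataFrame(rows)
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    return df


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            name = row.domain_id
            label = getattr(row, "label", None)
            if label:
                name = f"{name}|{label}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t+\n")


def read_variants(path: str | Path) -> pd.DataFrame:
    """Variant positions with class labels.

    Accepts a three-column TSV ``chrom pos class_label`` (1-based
    positions) or a minimal VCF whose INFO field carries ``CLASS=...``.
    """
    text = Path(path).read_text()
    if text.startswith("##fileformat") or text.startswith("#CHROM"):
        rows = []
        for line in text.splitlines():
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            info = parts[7] if len(parts) > 7 else ""
            cls = "variant"
            for kv in info.split(";"):
                if kv.startswith("CLASS="):
                    cls = kv[len("CLASS="):]
            rows.append({"chrom": parts[0], "pos": int(parts[1]), "class_label": cls})
        return pd.DataFrame(rows)
    with open(path) as fh:
        first = fh.readline()
    header = 0 if _has_header(first, ("chrom", "chr", "chromosome")) else None
    df = pd.read_csv(path, sep="\t", header=header, usecols=[0, 1, 2], dtype=str)
    df.columns = ["chrom", "pos", "class_label"]
    df["pos"] = df["pos"].astype(int)
    return df


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants[["chrom", "pos", "class_label"]].to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.lower().startswith("domain"):
            continue
        a, b = line.split("\t")[:2]
        edges.append((a, b))
    return edges


def write_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_a\tdomain_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gwas(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    header = 0 if _has_header(first, ("snp", "snp_id", "rsid")) else None
    df = pd.read_csv(path, sep="\t", header=header, usecols=[0, 1, 2, 3], dtype=str)
    df.columns = ["snp_id", "chrom", "pos", "p"]
    df["pos"] = df["pos"].astype(int)
    df["p"] = df["p"].astype(float)
    return df


def write_gwas(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas[["snp_id", "chrom", "pos", "p"]].to_csv(path, sep="\t", index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Gene models from BED (0-based half-open, converted to 1-based
    inclusive) or a 4/5-column TSV with a header (already 1-based)."""
    with open(path) as fh:
        first = fh.readline()
    if _has_header(first, ("gene", "gene_id")):
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        if "strand" not in df.columns:
            df["strand"] = "+"
        return df[["gene_id", "chrom", "start", "end", "strand"]]
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        rows.append(
            {
                "gene_id": parts[3],
                "chrom": parts[0],
                "start": int(parts[1]) + 1,
                "end": int(parts[2]),
                "strand": parts[5] if len(parts) > 5 else "+",
            }
        )
    return pd.DataFrame(rows)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def read_ps_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"domain_id": str, "pathway_id": str})


def write_ps_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
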