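"""Boolean domain-occurrence profiles and domain rarity weights.

A domain profile is a Boolean vector over the domain universe: entry
``c[k, l]`` is 1 iff protein *k* contains domain *l*.  Because prevalent
domains (e.g. generic binding folds) carry less information about pathway
membership than rare ones, each domain *j* receives a rarity weight

    omega_j = (total occurrences in the matrix) / (occurrences of j),

so a domain found in every protein has weight ~1 and a domain found once
has the largest weight.  These weights define the probability measure used
by the weighted mutual information in :mod:`psdnet.copathway`.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["build_profile_matrix", "compute_domain_weights"]


def build_profile_matrix(
    annotations: pd.DataFrame | Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Build the Boolean protein x domain occurrence matrix.

    Parameters
    ----------
    annotations
        Two-column table of ``(protein_id, domain_id)`` pairs, either a
        DataFrame whose first two columns are protein and domain, or any
        iterable of pairs.  Duplicate pairs collapse to a single occurrence.

    Returns
    -------
    pandas.DataFrame
        Integer 0/1 matrix, rows indexed by protein_id and columns by
        domain_id, both in lexicographic order so downstream outputs are
        deterministic.  Every row and column has at least one 1 (a pair
        list cannot produce an empty row or column).

    Raises
    ------
    ValueError
        If the annotation table is empty.
    """
    if isinstance(annotations, pd.DataFrame):
        if annotations.shape[1] < 2:
            raise ValueError("annotation table needs two columns")
        pairs = annotations.iloc[:, :2].copy()
        pairs.columns = ["protein_id", "domain_id"]
    else:
        pairs = pd.DataFrame(list(annotations), columns=["protein_id", "domain_id"])
    if len(pairs) == 0:
        raise ValueError("no annotations")

    n_dup = pairs.duplicated().sum()
    if n_dup:
        logger.info("collapsed %d duplicate annotation pairs", n_dup)
    pairs = pairs.drop_duplicates()

    matrix = (
        pd.crosstab(pairs["protein_id"], pairs["domain_id"])
        .clip(upper=1)
        .astype(np.int8)
    )
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "protein_id"
    matrix.columns.name = "domain_id"
    return matrix


def compute_domain_weights(matrix: pd.DataFrame) -> pd.Series:
    """Compute the rarity weight omega_j for every domain column.

    omega_j = (sum of all occurrences) / (occurrences of domain j); rarer
    domains get larger weights, and omega_j >= 1 always because no column
    can exceed the matrix total.

    Raises
    ------
    ValueError
        If any domain column has zero occurrences (cannot happen for a
        matrix built by :func:`build_profile_matrix`).
    """
    col_sums = matrix.sum(axis=0).astype(float)
    if (col_sums == 0).any():
        bad = list(matrix.columns[col_sums == 0])
        raise ValueError(f"domains with zero occurrences: {bad}")
    total = float(col_sums.sum())
    weights = total / col_sums
    weights.name = "omega"
    return weights
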