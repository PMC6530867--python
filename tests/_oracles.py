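"""Independent brute-force transcriptions of the scoring definitions.

Everything here is written as plain loops over dictionaries, directly from
the formulas, with none of the vectorised machinery of the package — these
are the oracles the implementation is checked against on small instances.
"""

from __future__ import annotations

import math
from itertools import combinations


def wmi_bruteforce(x, y, weights) -> float:
    """Mutual information of the weighted joint distribution, summed as
    sum_t p(t) * log(p(t) / (p_x(t1) * p_y(t2))) over the four states."""
    total = float(sum(weights))
    px = {0: 0.0, 1: 0.0}
    py = {0: 0.0, 1: 0.0}
    pxy = {(0, 0): 0.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 0.0}
    for xi, yi, w in zip(x, y, weights):
        px[int(xi)] += w / total
        py[int(yi)] += w / total
        pxy[(int(xi), int(yi))] += w / total
    mi = 0.0
    for (t1, t2), p in pxy.items():
        if p > 0:
            mi += p * math.log(p / (px[t1] * py[t2]))
    return mi


def lls_bruteforce(pairs_sorted, positives, negatives, bin_size) -> dict:
    """Per-pair LLS by literal binning: walk pairs in the given order in
    bins of ``bin_size``, merge a bin forward while it lacks gold positives
    or negatives, merge a trailing deficient/partial bin backward, then
    assign ln((pos/neg) / prior_odds) to every pair of the bin."""
    prior = len(positives) / len(negatives)
    bins = []
    i = 0
    n = len(pairs_sorted)
    while i < n:
        j = min(i + bin_size, n)
        members = pairs_sorted[i:j]
        npos = sum(1 for p in members if p in positives)
        nneg = sum(1 for p in members if p in negatives)
        while (npos == 0 or nneg == 0) and j < n:
            k = min(j + bin_size, n)
            npos += sum(1 for p in pairs_sorted[j:k] if p in positives)
            nneg += sum(1 for p in pairs_sorted[j:k] if p in negatives)
            j = k
        bins.append([i, j, npos, nneg])
        i = j
    while len(bins) > 1 and (
        bins[-1][2] == 0 or bins[-1][3] == 0 or bins[-1][1] - bins[-1][0] < bin_size
    ):
        last = bins.pop()
        bins[-1][1] = last[1]
        bins[-1][2] += last[2]
        bins[-1][3] += last[3]
    out = {}
    for i, j, npos, nneg in bins:
        lls = math.log((npos / nneg) / prior)
        for p in pairs_sorted[i:j]:
            out[p] = lls
    return out


def pareto_ppa_bruteforce(sums_by_protein: dict) -> dict:
    """PPA for one pathway from the per-protein link sums: fit
    s_min = min positive sum, alpha = max(1, 1 + n / sum(ln(s/s_min)))
    over the positive sums, then PPA = 1 - (s_min/s)^alpha (0 for s = 0)."""
    positive = [s for s in sums_by_protein.values() if s > 0]
    if not positive:
        return {p: 0.0 for p in sums_by_protein}
    s_min = min(positive)
    spread = sum(math.log(s / s_min) for s in positive)
    alpha = math.inf if spread == 0 else max(1.0, 1.0 + len(positive) / spread)
    out = {}
    for p, s in sums_by_protein.items():
        if s <= 0:
            out[p] = 0.0
        elif math.isinf(alpha):
            out[p] = 0.0 if s <= s_min else 1.0
        else:
            out[p] = 1.0 - (s_min / s) ** alpha
    return out


def scores_bruteforce(edges, pathways, carriers):
    """PPA/DPA/GI/PS by direct transcription.

    edges: iterable of (protein_a, protein_b, lls), the positive-LLS network.
    pathways: pathway_id -> set of member proteins.
    carriers: domain_id -> set of carrier proteins (occurrence matrix by column).

    Returns (ppa, dpa, gini, ps) as nested dicts keyed [protein/domain][pathway].
    """
    adj: dict[str, dict[str, float]] = {}
    for a, b, lls in edges:
        adj.setdefault(a, {})[b] = lls
        adj.setdefault(b, {})[a] = lls
    proteins = sorted(adj)

    ppa: dict[str, dict[str, float]] = {p: {} for p in proteins}
    for f, members in pathways.items():
        sums = {}
        for p in proteins:
            sums[p] = sum(lls for q, lls in adj[p].items() if q in members)
        col = pareto_ppa_bruteforce(sums)
        for p in proteins:
            ppa[p][f] = col[p]

    dpa: dict[str, dict[str, float]] = {}
    for d, carr in carriers.items():
        in_net = [p for p in sorted(carr) if p in adj]
        if not in_net:
            continue
        dpa[d] = {}
        for f in pathways:
            dpa[d][f] = sum(ppa[p][f] for p in in_net) / len(in_net)

    gini = {}
    ps: dict[str, dict[str, float]] = {}
    for d, row in dpa.items():
        total = sum(row.values())
        if total == 0:
            gini[d] = float("nan")
            ps[d] = {f: 0.0 for f in row}
            continue
        gini[d] = 1.0 - sum((v / total) ** 2 for v in row.values())
        ps[d] = {f: (1.0 - gini[d]) * v for f, v in row.items()}
    return ppa, dpa, gini, ps


def hypergeom_tail_bruteforce(overlap, universe, n_set_a, n_set_b) -> float:
    """P(X >= overlap) for the overlap of two sets drawn from a universe,
    by explicit summation of hypergeometric terms."""
    total = 0.0
    for k in range(overlap, min(n_set_a, n_set_b) + 1):
        total += (
            math.comb(n_set_a, k)
            * math.comb(universe - n_set_a, n_set_b - k)
            / math.comb(universe, n_set_b)
        )
    return total


def fisher_greater_bruteforce(a, b, c, d) -> float:
    """One-sided (enrichment) Fisher's exact p for [[a, b], [c, d]] via the
    hypergeometric tail: margins fixed, P(top-left >= a)."""
    return hypergeom_tail_bruteforce(a, a + b + c + d, a + b, a + c)


def gold_pairs_bruteforce(pathways, proteins):
    """Positive/negative co-pathway pairs by exhaustive enumeration."""
    member = {}
    universe = set(proteins)
    for f, ms in pathways.items():
        for p in set(ms) & universe:
            member.setdefault(p, set()).add(f)
    pos, neg = set(), set()
    for a, b in combinations(sorted(member), 2):
        if member[a] & member[b]:
            pos.add((a, b))
        else:
            neg.add((a, b))
    return pos, neg
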