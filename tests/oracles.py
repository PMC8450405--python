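"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: aggregation is a plain
per-cell Python loop, the rank-sum null is fully enumerated, and Pearson r
is the textbook covariance formula.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np


def brute_force_activity(kb, values_df):
    """Enumerate every gene of every group per sample with explicit loops."""
    out = {}
    for rx in kb.reactions:
        row = {}
        for sample in values_df.columns:
            best_val, best_gene = None, None
            for gene in rx.gene_group.members:
                v = float(values_df.at[gene, sample])
                if best_val is None:
                    best_val, best_gene = v, gene
                elif rx.gene_group.semantics == "ALTERNATIVES" and v > best_val:
                    best_val, best_gene = v, gene
                elif rx.gene_group.semantics == "COMPLEX" and v < best_val:
                    best_val, best_gene = v, gene
            row[sample] = (best_val, best_gene)
        out[rx.reaction_id] = row
    return out


def exact_ranksum_pvalue(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments.

    Tie-free inputs only. U is the count of (a_i, b_j) pairs with a_i > b_j;
    the two-sided p is twice the smaller tail of the enumerated null,
    capped at 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2

    total = comb(na + nb, na)
    null_u = []
    all_ranks = range(1, na + nb + 1)
    for subset in combinations(all_ranks, na):
        null_u.append(sum(subset) - na * (na + 1) / 2)
    null_u = np.asarray(null_u)
    p_le = float(np.sum(null_u <= u_obs)) / total
    p_ge = float(np.sum(null_u >= u_obs)) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def pearson_r_formula(x, y) -> float:
    """Pearson r via the covariance formula, no numpy statistics helpers."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / sqrt(vx * vy)
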