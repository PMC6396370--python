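"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and the textbook formulas,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def pooled_t(a, b):
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    return ma - mb, se


def brute_force_permutation_fdr(rows, n_a, s0, fdr):
    """Exhaustive SAM-style permutation FDR on a list of per-protein rows.

    rows: list of value tuples; the first n_a columns are group A.
    Returns (threshold, significant list, q list, fdr_at dict).
    """
    n = len(rows[0])

    def abs_stat(row, idx_a):
        a = [row[i] for i in idx_a]
        b = [row[i] for i in range(n) if i not in idx_a]
        d, se = pooled_t(a, b)
        return abs(d / (se + s0))

    obs = [abs_stat(row, set(range(n_a))) for row in rows]
    assignments = list(itertools.combinations(range(n), n_a))
    null_stats = [
        [abs_stat(row, set(c)) for row in rows] for c in assignments
    ]

    candidates = sorted(obs)
    fdr_at = []
    for c in candidates:
        obs_count = sum(1 for s in obs if s >= c)
        total_null = sum(
            sum(1 for s in perm_stats if s >= c) for perm_stats in null_stats
        )
        mean_null = total_null / len(assignments)
        fdr_at.append(min(1.0, mean_null / max(1, obs_count)))

    threshold = math.inf
    for c, f in zip(candidates, fdr_at):
        if f <= fdr:
            threshold = c
            break
    significant = [s >= threshold for s in obs]
    q = [
        min(f for c, f in zip(candidates, fdr_at) if c <= s)
        for s in obs
    ]
    return threshold, significant, q


def brute_force_bh(p_values):
    """Step-up Benjamini-Hochberg by the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def pearson_r(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
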