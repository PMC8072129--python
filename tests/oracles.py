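"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain Python loops, no shared code with the package.
The chi-square helper works in exact rational arithmetic so that ties
between adjacent pairs are mathematical ties, not rounding accidents.
"""

from __future__ import annotations

from fractions import Fraction


def chi2_2x2(table) -> Fraction:
    """Sum (observed - expected)^2 / expected over a 2x2 integer table,
    zero-expected cells contributing zero; exact rational result."""
    rows = [sum(r) for r in table]
    cols = [table[0][j] + table[1][j] for j in range(2)]
    total = sum(rows)
    if total == 0:
        return Fraction(0)
    stat = Fraction(0)
    for i in range(2):
        for j in range(2):
            expected = Fraction(int(rows[i]) * int(cols[j]), int(total))
            if expected > 0:
                stat += (int(table[i][j]) - expected) ** 2 / expected
    return stat


def chimerge_greedy(values, labels, target_bins):
    """Exhaustive greedy ChiMerge: one bin per distinct value, then repeatedly
    merge the leftmost adjacent pair with the smallest chi-square, recomputing
    every pairwise statistic from scratch at each step. Returns the cut points
    (right edges of all bins but the last)."""
    distinct = sorted(set(values))
    bins = []
    for v in distinct:
        c0 = sum(1 for x, y in zip(values, labels) if x == v and y == 0)
        c1 = sum(1 for x, y in zip(values, labels) if x == v and y == 1)
        bins.append([v, c0, c1])
    while len(bins) > target_bins:
        best_i, best_stat = None, None
        for i in range(len(bins) - 1):
            stat = chi2_2x2([[bins[i][1], bins[i][2]],
                             [bins[i + 1][1], bins[i + 1][2]]])
            if best_stat is None or stat < best_stat:
                best_i, best_stat = i, stat
        merged = [bins[best_i + 1][0],
                  bins[best_i][1] + bins[best_i + 1][1],
                  bins[best_i][2] + bins[best_i + 1][2]]
        bins[best_i:best_i + 2] = [merged]
    return [b[0] for b in bins[:-1]]


def average_ranks(values):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Pearson correlation of average ranks, computed by plain sums."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


def auc_pairs(scores, labels) -> float:
    """Concordant-pair count over all positive-negative pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
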