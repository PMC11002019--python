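"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths (and scipy's rank/test
helpers) so that they can serve as references for the implementations.
"""

from math import comb


def average_ranks(values):
    """Fractional (average-tie) ranks, 1-based, computed from first principles."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of positions i..j, 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_directed_score(sample_values, weights):
    """Mean directed rank over the set genes present in the sample.

    ``sample_values``: dict gene -> expression; ``weights``: dict gene -> +-1.
    """
    genes = list(sample_values)
    ranks = average_ranks([sample_values[g] for g in genes])
    rank_of = dict(zip(genes, ranks))
    g_total = len(genes)
    used = [g for g in weights if g in rank_of]
    if not used:
        raise ValueError("no overlap")
    total = 0.0
    for g in used:
        r = rank_of[g]
        total += r if weights[g] == +1 else g_total + 1 - r
    return total / len(used), len(used)


def brute_force_fisher_2x2(table):
    """Two-sided Fisher P by direct enumeration over all tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(first cell = x | margins)
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-7))


def brute_force_u_statistic(x, y):
    """U = #{x_i > y_j} + 0.5 #{x_i = y_j} by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u
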