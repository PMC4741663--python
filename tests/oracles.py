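"""Independent brute-force oracles used to check the package's statistics.

These deliberately avoid the code paths (and, where feasible, the library
routines) they validate: BH by literal step-up recursion, the 2xK exact
test by full enumeration of fixed-margin tables, Welch's t from the
textbook formulas, and Kruskal-Wallis from explicit ranks.
"""

import itertools
import math

import numpy as np


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = list(p_values)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def welch_t_formula(a, b):
    """Welch statistic, Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def permutation_t_p(a, b):
    """Exact two-sided permutation p-value of the Welch statistic."""
    pooled = list(a) + list(b)
    na = len(a)
    t_obs = abs(welch_t_formula(a, b)[0])
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(welch_t_formula(ga, gb)[0]) >= t_obs - 1e-12:
            hits += 1
    return hits / total


def _log_table_prob(table, log_fact):
    """Exact fixed-margin probability (log) of a 2xK table."""
    table = np.asarray(table, int)
    n = table.sum()
    logp = sum(log_fact[m] for m in table.sum(axis=1))
    logp += sum(log_fact[m] for m in table.sum(axis=0))
    logp -= log_fact[n]
    logp -= sum(log_fact[x] for x in table.ravel())
    return logp


def exact_2xk_p(table):
    """Freeman-Halton p by full enumeration of 2xK tables with fixed margins."""
    table = np.asarray(table, int)
    row0 = int(table[0].sum())
    cols = table.sum(axis=0)
    n = int(table.sum())
    log_fact = [math.lgamma(i + 1) for i in range(n + 1)]
    logp_obs = _log_table_prob(table, log_fact)

    k = len(cols)
    p_total = 0.0

    def recurse(j, remaining, first_row):
        nonlocal p_total
        if j == k - 1:
            if remaining <= cols[j]:
                cand = first_row + [remaining]
                t = np.vstack([cand, cols - cand])
                logp = _log_table_prob(t, log_fact)
                if logp <= logp_obs + 1e-9:
                    p_total += math.exp(logp)
            return
        for x in range(0, min(int(cols[j]), remaining) + 1):
            recurse(j + 1, remaining - x, first_row + [x])

    recurse(0, row0, [])
    return p_total


def kruskal_h_from_ranks(groups):
    """Kruskal-Wallis H with tie correction, computed from explicit ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos : pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    seen = {}
    for v in pooled:
        seen[v] = seen.get(v, 0) + 1
    for count in seen.values():
        ties += count**3 - count
    correction = 1.0 - ties / (n**3 - n)
    return h / correction
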