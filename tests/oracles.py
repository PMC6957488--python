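"""Independent brute-force reference implementations used only as test
oracles. Deliberately written as plain double loops / direct formulas,
sharing no code with the package."""

import math
from itertools import combinations

import numpy as np


def sampen_bruteforce(x, m, r):
    """Sample entropy by direct enumeration of all template pairs.

    Returns (A, B, value); value is +inf when A == 0, None when B == 0.
    """
    x = list(map(float, x))
    n = len(x)
    nt = n - m
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    if b == 0:
        return a, b, None
    if a == 0:
        return a, b, math.inf
    return a, b, -math.log(a / b)


def fuzzyen_bruteforce(x, m, r, n_power):
    """Fuzzy entropy by direct double-loop evaluation."""
    x = list(map(float, x))
    k = len(x) - m

    def phi(length):
        tpls = []
        for i in range(k):
            t = x[i:i + length]
            mu = sum(t) / length
            tpls.append([v - mu for v in t])
        sims = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                d = max(abs(p - q) for p, q in zip(tpls[i], tpls[j]))
                sims.append(math.exp(-((d / r) ** n_power)))
        return sum(sims) / len(sims)

    return math.log(phi(m)) - math.log(phi(m + 1))


def coarse_grain_bruteforce(x, tau):
    out = []
    for j in range(len(x) // tau):
        block = x[j * tau:(j + 1) * tau]
        out.append(sum(block) / tau)
    return out


def trapezoid_bruteforce(values):
    total = 0.0
    for i in range(len(values) - 1):
        total += 0.5 * (values[i] + values[i + 1])
    return total


def midrank(values):
    """Average ranks with tie midranks (1-based)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """Pearson correlation of midranks, computed longhand."""
    rx = midrank(list(x))
    ry = midrank(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def anova_bruteforce(groups):
    """One-way F by explicit sums of squares."""
    allv = [v for g in groups for v in g]
    n = len(allv)
    k = len(groups)
    grand = sum(allv) / n
    ssb = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = k - 1
    dfw = n - k
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def permutation_exhaustive(a, b):
    """Two-sided exact permutation p for the mean difference by full
    enumeration of label splits."""
    pooled = list(a) + list(b)
    na = len(a)
    obs = sum(a) / na - sum(b) / len(b)
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        stat = sum(ga) / len(ga) - sum(gb) / len(gb)
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def pooled_t_squared(a, b):
    """Square of the pooled-variance two-sample t statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t * t
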