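"""Numba kernels for the O(N^2) template-matching inner loops.

Kept separate so the public entropy module stays readable; both kernels are
deliberately simple nested loops (the brute-force structure is the
definition) and rely on JIT compilation for speed at N ~ 16,000.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts(x, m, r):
    """Count template matches of length m (B) and m+1 (A).

    Templates are x[i:i+m] for i = 0..N-m-1 (both lengths use the same
    index range, so self-matches are excluded and every m-template has an
    m+1 extension). A pair matches when the Chebyshev distance is
    strictly below r.
    """
    nt = x.shape[0] - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) >= r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, b


@njit(cache=True)
def fuzzy_phi(tpl, r, n):
    """Mean fuzzy similarity exp(-(d/r)^n) over ordered pairs i != j.

    tpl is the (K, d) matrix of baseline-removed templates; d is the
    Chebyshev distance. The mean over ordered pairs equals the mean over
    unordered pairs because the similarity is symmetric.
    """
    k = tpl.shape[0]
    d = tpl.shape[1]
    total = 0.0
    for i in range(k - 1):
        for j in range(i + 1, k):
            dmax = 0.0
            for q in range(d):
                dv = abs(tpl[i, q] - tpl[j, q])
                if dv > dmax:
                    dmax = dv
            total += np.exp(-((dmax / r) ** n))
    return total / (k * (k - 1) / 2.0)
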