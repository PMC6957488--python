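"""Condition-group comparisons: one-way F omnibus and seeded permutation
posttests.

The study design yields five condition groups (blank control and four
stimulation temperatures) with 30 + 4x29 = 146 observations, hence the
omnibus degrees of freedom (4, 141). The omnibus is the classical one-way
independent-design F; pairwise contrasts use a label-shuffling permutation
test on the difference of group means (exhaustive for pooled n <= 10),
two-sided, with the +1 add-one correction. No multiplicity correction is
applied by default (a Holm option exists), and significance is alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DegenerateSignalError, DesignError, ParameterError
from .records import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "PermutationResult",
    "ConditionComparison",
    "oneway_anova",
    "permutation_pairwise",
    "compare_conditions",
]


@dataclass
class AnovaResult:
    """One-way F with its degrees of freedom; F is NaN (flagged in
    ``note``) when every group has zero within-group variance."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_ns: tuple
    note: str = ""


@dataclass
class PermutationResult:
    """Two-sided permutation test on the difference of group means.

    ``p = (1 + #{|perm stat| >= |observed|}) / (1 + n_perm)`` in sampled
    mode; in exhaustive mode the exact proportion over all label splits.
    """

    statistic: float
    p: float
    n_perm: int
    seed: int | None
    pair: tuple
    exhaustive: bool = False
    note: str = ""


def oneway_anova(groups) -> AnovaResult:
    """Classical one-way independent-design ANOVA.

    ``groups`` is a list of >= 2 numeric sequences, each with >= 2
    observations. p comes from the F(k-1, N-k) distribution.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ParameterError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ParameterError("each group needs at least 2 observations")
    ns = tuple(int(a.size) for a in arrs)
    n_total = sum(ns)
    grand = sum(a.sum() for a in arrs) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = k - 1
    df_w = n_total - k
    if ss_within == 0:
        logger.warning("one-way F undefined: zero within-group variance everywhere")
        return AnovaResult(F=math.nan, df_between=df_b, df_within=df_w,
                           p=math.nan, group_ns=ns,
                           note="undefined: zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w,
                       p=p, group_ns=ns)


def permutation_pairwise(a, b, n_perm: int = 10_000, seed: int | None = None,
                         alternative: str = "two_sided") -> PermutationResult:
    """Seeded label-shuffling test on mean(a) - mean(b).

    For pooled n <= 10 all C(n, n_a) label splits are enumerated and the
    p-value is exact; otherwise ``n_perm`` seeded shuffles are drawn and
    the +1-corrected estimate returned. The test is symmetric: swapping
    the groups flips the statistic's sign but leaves p unchanged for the
    same seed (the groups are canonicalized internally).
    """
    if alternative != "two_sided":
        raise ParameterError("only the two-sided alternative is implemented")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")

    # canonical internal order so (a, b) and (b, a) share the permutation
    # stream; the reported statistic keeps the caller's orientation
    flip = (b.size, tuple(b)) > (a.size, tuple(a))
    g1, g2 = (b, a) if flip else (a, b)
    obs_internal = g1.mean() - g2.mean()
    observed = -obs_internal if flip else obs_internal

    pooled = np.concatenate([g1, g2])
    n1 = g1.size
    if np.ptp(pooled) == 0:
        logger.warning("permutation test degenerate: pooled values constant")
        return PermutationResult(statistic=float(observed), p=1.0, n_perm=0,
                                 seed=seed, pair=(), exhaustive=True,
                                 note="degenerate: zero pooled variance")

    thresh = abs(obs_internal) - 1e-12
    if pooled.size <= 10:
        total = 0
        count = 0
        idx_all = set(range(pooled.size))
        pooled_sum = pooled.sum()
        for comb in combinations(range(pooled.size), n1):
            s1 = pooled[list(comb)].sum()
            stat = s1 / n1 - (pooled_sum - s1) / (pooled.size - n1)
            if abs(stat) >= thresh:
                count += 1
            total += 1
        return PermutationResult(statistic=float(observed), p=count / total,
                                 n_perm=total, seed=seed, pair=(),
                                 exhaustive=True)

    rng = np.random.default_rng(seed)
    mat = np.tile(pooled, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    stats_perm = mat[:, :n1].mean(axis=1) - mat[:, n1:].mean(axis=1)
    count = int(np.sum(np.abs(stats_perm) >= thresh))
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(statistic=float(observed), p=float(p),
                             n_perm=n_perm, seed=seed, pair=())


@dataclass
class ConditionComparison:
    """Omnibus F plus the full pairwise permutation matrix."""

    anova: AnovaResult
    pairwise: dict
    alpha: float
    n_perm: int
    seed: int
    holm: bool = False
    significant: dict = field(default_factory=dict)

    def p_matrix(self, conditions=CONDITIONS) -> np.ndarray:
        k = len(conditions)
        mat = np.full((k, k), np.nan)
        for (ca, cb), res in self.pairwise.items():
            i, j = conditions.index(ca), conditions.index(cb)
            mat[i, j] = mat[j, i] = res.p
        return mat


def compare_conditions(values_by_condition: dict, n_perm: int = 10_000,
                       seed: int = 0, alpha: float = 0.05,
                       holm: bool = False,
                       conditions=CONDITIONS) -> ConditionComparison:
    """Omnibus one-way F across the condition groups plus all pairwise
    permutation posttests at ``alpha`` (no multiplicity correction unless
    ``holm=True``)."""
    missing = [c for c in conditions if c not in values_by_condition
               or len(values_by_condition[c]) == 0]
    if missing:
        raise DesignError(f"missing condition groups: {missing}")
    groups = [np.asarray(values_by_condition[c], dtype=float) for c in conditions]
    anova = oneway_anova(groups)
    pairs = list(combinations(range(len(conditions)), 2))
    root = np.random.SeedSequence([seed, 13])
    pair_seeds = root.generate_state(len(pairs))
    pairwise = {}
    for (i, j), ps in zip(pairs, pair_seeds):
        ca, cb = conditions[i], conditions[j]
        res = permutation_pairwise(groups[i], groups[j], n_perm=n_perm,
                                   seed=int(ps))
        res.pair = (ca, cb)
        pairwise[(ca, cb)] = res
    if holm:
        keys = sorted(pairwise, key=lambda k: pairwise[k].p)
        m = len(keys)
        sig = {}
        running = True
        for rank, key in enumerate(keys):
            ok = running and pairwise[key].p <= alpha / (m - rank)
            sig[key] = bool(ok)
            running = ok
    else:
        sig = {key: bool(res.p < alpha) for key, res in pairwise.items()}
    return ConditionComparison(anova=anova, pairwise=pairwise, alpha=alpha,
                               n_perm=n_perm, seed=seed, holm=holm,
                               significant=sig)
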