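"""Spearman rank correlations between perfusion and oxygenation.

Two analyses share the machinery: per-subject time-domain correlations
between each speed-resolved perfusion component and the oxygen-saturation
series within a protocol epoch, and cross-subject correlations between the
complexity area indices (CAIs) of the two signals within a condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, ParameterError
from .records import EpochSpec, SignalRecord
from .signal_io import extract_window, minute_average

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "spearman",
    "timecourse_correlations",
    "cai_correlations",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS = (("V1", "oxy_sat"), ("V2", "oxy_sat"), ("V3", "oxy_sat"))


@dataclass
class CorrelationResult:
    """Spearman rho for a named pair, with sample size and p-value.

    ``rho`` is NaN (and ``note`` explains why) when either input has zero
    rank variance. ``p`` is two-sided: a large-sample t approximation by
    default, or the exact permutation distribution for n <= 10 when
    requested.
    """

    pair: tuple[str, str]
    condition: str
    epoch: str
    rho: float
    n: int
    p: float
    note: str = ""


def _midrank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def spearman(x, y, condition: str = "", epoch: str = "",
             pair: tuple[str, str] = ("x", "y"),
             p_method: str = "t") -> CorrelationResult:
    """Spearman correlation (mid-ranks for ties) with a two-sided p.

    ``p_method='t'`` uses the large-sample t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df; ``p_method='exact'``
    enumerates all permutations of one ranking (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 observations")
    rho = _midrank_rho(x, y)
    if math.isnan(rho):
        logger.warning("spearman undefined: an input has zero rank variance")
        return CorrelationResult(pair=pair, condition=condition, epoch=epoch,
                                 rho=math.nan, n=n, p=math.nan,
                                 note="undefined: constant input")
    if p_method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    elif p_method == "exact":
        if n > 10:
            raise ParameterError("exact permutation p limited to n <= 10")
        p = _exact_spearman_p(x, y, rho)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")
    return CorrelationResult(pair=pair, condition=condition, epoch=epoch,
                             rho=rho, n=n, p=p)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p over all n! permutations of the y ranking."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ryc = ry - ry.mean()
    sy = ry.std()
    n = rx.size
    count = 0
    total = 0
    chunk: list = []
    for perm in permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _chunk_count(rx, ryc, sy, chunk, abs(rho_obs))
            total += len(chunk)
            chunk = []
    if chunk:
        count += _chunk_count(rx, ryc, sy, chunk, abs(rho_obs))
        total += len(chunk)
    return count / total


def _chunk_count(rx, ryc, sy, chunk, thresh) -> int:
    idx = np.asarray(chunk)
    rhos = (ryc[idx] @ rx) / (rx.size * sy)
    return int(np.sum(np.abs(rhos) >= thresh - 1e-12))


def timecourse_correlations(records: list[SignalRecord], spec: EpochSpec,
                            epoch: str = "stimulation",
                            pairs=DEFAULT_PAIRS,
                            after_window: str | None = None,
                            use_minute_means: bool = False) -> pd.DataFrame:
    """Per-subject time-domain Spearman rho within one protocol window.

    ``epoch`` names a protocol epoch; alternatively ``after_window``
    ("stimulation", "post" or "both") selects the post-stimulation
    analysis window. Raw epoch samples are correlated by default;
    ``use_minute_means=True`` correlates the centred one-minute means
    instead.

    Returns a tidy frame (subject_id, group, condition, epoch, pair, rho,
    n, p); recordings missing a channel are skipped with a warning.
    """
    if after_window is not None:
        window = spec.after_window(after_window)
        epoch_label = f"after:{after_window}"
    else:
        window = spec.window(epoch)
        epoch_label = epoch
    by_key = {rec.key(): rec for rec in records}
    subjects = sorted({(r.subject_id, r.group, r.condition) for r in records})
    rows = []
    for subject_id, group, condition in subjects:
        for chan_a, chan_b in pairs:
            rec_a = by_key.get((subject_id, condition, chan_a))
            rec_b = by_key.get((subject_id, condition, chan_b))
            if rec_a is None or rec_b is None:
                logger.warning("skipping %s/%s pair (%s, %s): channel missing",
                               subject_id, condition, chan_a, chan_b)
                continue
            a = extract_window(rec_a, *window)
            b = extract_window(rec_b, *window)
            if use_minute_means:
                xa = minute_average(a)[1]
                xb = minute_average(b)[1]
            else:
                xa, xb = a.values, b.values
            res = spearman(xa, xb, condition=condition, epoch=epoch_label,
                           pair=(chan_a, chan_b))
            rows.append({"subject_id": subject_id, "group": group,
                         "condition": condition, "epoch": epoch_label,
                         "pair": f"{chan_a}~{chan_b}", "rho": res.rho,
                         "n": res.n, "p": res.p})
    return pd.DataFrame(rows)


def cai_correlations(cai_table: pd.DataFrame, condition: str,
                     pairs=DEFAULT_PAIRS) -> list[CorrelationResult]:
    """Cross-subject Spearman rho between channel CAIs within a condition.

    ``cai_table`` is tidy with columns subject_id, condition, channel,
    cai. Subjects with a missing (NaN) CAI in either channel of a pair are
    dropped pairwise; fewer than 3 complete pairs is an error.
    """
    sub = cai_table[cai_table["condition"] == condition]
    wide = sub.pivot_table(index="subject_id", columns="channel",
                           values="cai", aggfunc="first")
    results = []
    for chan_a, chan_b in pairs:
        if chan_a not in wide.columns or chan_b not in wide.columns:
            raise DegenerateSignalError(
                f"condition {condition!r}: channel {chan_a!r} or {chan_b!r} "
                f"has no CAIs")
        both = wide[[chan_a, chan_b]].dropna()
        if len(both) < 3:
            raise DegenerateSignalError(
                f"condition {condition!r}: fewer than 3 complete CAI pairs "
                f"for ({chan_a}, {chan_b})")
        res = spearman(both[chan_a].to_numpy(), both[chan_b].to_numpy(),
                       condition=condition, epoch="", pair=(chan_a, chan_b))
        results.append(res)
    return results
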