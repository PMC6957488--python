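"""Multiscale entropy analysis: SampEn, FuzzyEn, MSE/MFE curves and the
complexity area index (CAI).

The multiscale procedure has three steps: (1) coarse-grain the series into
non-overlapping block means at scales tau = 1..max_scale; (2) compute the
sample entropy (MSE) or fuzzy entropy (MFE) of each coarse-grained series;
(3) integrate the entropy-versus-scale curve (trapezoid rule, unit scale
spacing) to obtain the CAI, a scalar complexity summary.

Conventions
-----------
* Sample entropy: templates of length ``m`` taken at i = 0..N-m-1 (the same
  index range as the length m+1 templates, the Richman-Moorman convention),
  Chebyshev distance strictly below the absolute tolerance, self-matches
  excluded. SampEn = -ln(A/B). When no m-template pair extends to an
  m+1 match (A = 0) the value is +inf — an *undefined* sentinel, and any
  CAI over a curve containing it is reported missing (NaN) rather than
  interpolated.
* Fuzzy entropy: each template has its own mean subtracted; hard matching
  is replaced by the membership exp(-(d/r)^n) with fuzzy power ``n``;
  FuzzyEn = ln(phi_m) - ln(phi_{m+1}) with phi the mean similarity over
  ordered pairs i != j.
* The tolerance is ``r`` times the population SD (ddof=0) of the original
  series by default, reused unchanged at every scale (``fixed_original_sd``);
  ``per_scale_sd`` recomputes it from each coarse-grained series.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import fuzzy_phi, sampen_counts
from .errors import DegenerateSignalError, ParameterError, RangeError

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyParams",
    "EntropyCurve",
    "coarse_grain",
    "sample_entropy",
    "fuzzy_entropy",
    "mse_curve",
    "mfe_curve",
    "cai",
]


@dataclass(frozen=True)
class EntropyParams:
    """Configuration of the multiscale entropy analysis.

    Attributes
    ----------
    m : int
        Embedding (template) dimension, default 2.
    r : float
        Tolerance as a fraction of the signal SD, default 0.15. Values
        outside (0, 0.5] are allowed but trigger a warning — matching
        becomes either too sparse or indiscriminate.
    fuzzy_power : float
        Exponent n of the fuzzy membership exp(-(d/r)^n), default 2.
    max_scale : int
        Largest coarse-graining factor, default 20.
    r_mode : {"fixed_original_sd", "per_scale_sd"}
        Whether the absolute tolerance is fixed from the scale-1 SD or
        recomputed per scale.
    """

    m: int = 2
    r: float = 0.15
    fuzzy_power: float = 2.0
    max_scale: int = 20
    r_mode: str = "fixed_original_sd"

    def __post_init__(self):
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ParameterError("m must be a positive integer")
        if not (np.isfinite(self.r) and self.r > 0):
            raise ParameterError("r must be positive and finite")
        if not (0 < self.r <= 0.5):
            warnings.warn(
                f"tolerance r={self.r} outside the usual (0, 0.5] range",
                stacklevel=2,
            )
        if not (np.isfinite(self.fuzzy_power) and self.fuzzy_power > 0):
            raise ParameterError("fuzzy_power must be positive")
        if not (isinstance(self.max_scale, (int, np.integer)) and self.max_scale >= 1):
            raise ParameterError("max_scale must be a positive integer")
        if self.r_mode not in ("fixed_original_sd", "per_scale_sd"):
            raise ParameterError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class EntropyCurve:
    """Per-scale entropy values and their integral.

    ``values[t-1]`` is the entropy of the scale-``t`` coarse-grained series;
    ``cai`` is the trapezoidal integral over the scale axis, NaN if any
    scale is undefined; ``n_effective[t-1] = floor(N/t)``.
    """

    kind: str  # "MSE" or "MFE"
    scales: np.ndarray
    values: np.ndarray
    cai: float
    n_effective: np.ndarray


def coarse_grain(x, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; the tail of fewer
    than ``tau`` samples is discarded (length becomes floor(N/tau))."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (isinstance(tau, (int, np.integer)) and 1 <= tau <= n):
        raise ParameterError(f"tau must be an integer in [1, {n}], got {tau}")
    tau = int(tau)
    if tau == 1:
        return x.copy()
    nblk = n // tau
    return x[: nblk * tau].reshape(nblk, tau).mean(axis=1)


def _check_series(x, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if x.size < m + 2:
        raise RangeError(f"series of length {x.size} too short for m={m}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("series must be finite")
    return x


def sample_entropy(x, m: int, r_abs: float) -> float:
    """Sample entropy -ln(A/B) with absolute tolerance ``r_abs``.

    Returns +inf when A = 0 (undefined; no m-match extends).
    Raises :class:`DegenerateSignalError` when B = 0 (the tolerance
    resolves no template pairs at all).
    """
    x = _check_series(x, m)
    if not (np.isfinite(r_abs) and r_abs > 0):
        raise ParameterError("r_abs must be positive and finite")
    a, b = sampen_counts(x, int(m), float(r_abs))
    if b == 0:
        raise DegenerateSignalError(
            "no template matches at length m: tolerance too small for this signal"
        )
    if a == 0:
        return math.inf
    return -math.log(a / b)


def fuzzy_entropy(x, m: int, r_abs: float, n: float = 2.0) -> float:
    """Fuzzy entropy ln(phi_m) - ln(phi_{m+1}) with fuzzy power ``n``.

    Templates are baseline-removed (own mean subtracted); similarity is
    exp(-(d/r_abs)^n) with Chebyshev d. Continuous in ``r_abs`` and equal
    to 0 for a constant series.
    """
    x = _check_series(x, m)
    if not (np.isfinite(r_abs) and r_abs > 0):
        raise ParameterError("r_abs must be positive and finite")
    if not (np.isfinite(n) and n > 0):
        raise ParameterError("fuzzy power must be positive")
    m = int(m)
    k = x.size - m  # same template count for both lengths
    tpl_m = np.lib.stride_tricks.sliding_window_view(x, m)[:k]
    tpl_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:k]
    tpl_m = np.ascontiguousarray(tpl_m - tpl_m.mean(axis=1, keepdims=True))
    tpl_m1 = np.ascontiguousarray(tpl_m1 - tpl_m1.mean(axis=1, keepdims=True))
    phi_m = fuzzy_phi(tpl_m, float(r_abs), float(n))
    phi_m1 = fuzzy_phi(tpl_m1, float(r_abs), float(n))
    if phi_m <= 0 or phi_m1 <= 0:
        raise DegenerateSignalError("fuzzy similarities underflowed to zero")
    return math.log(phi_m) - math.log(phi_m1)


def cai(values, rule: str = "trapezoid") -> float:
    """Complexity area index: the integral of the entropy curve over the
    scale axis (unit spacing).

    A curve with any undefined (non-finite) value yields NaN — the CAI is
    reported missing rather than interpolated.
    """
    if rule != "trapezoid":
        raise ParameterError(f"unknown integration rule {rule!r}")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateSignalError("CAI needs at least 2 scales")
    if not np.all(np.isfinite(values)):
        return math.nan
    return float(np.trapezoid(values))


def _curve(x, params: EntropyParams, kind: str) -> EntropyCurve:
    x = _check_series(x, params.m)
    n = x.size
    max_scale = params.max_scale
    if n // max_scale < params.m + 2:
        reduced = n // (params.m + 2)
        if reduced < 1:
            raise RangeError(f"series of length {n} too short for any scale")
        logger.warning(
            "max_scale reduced from %d to %d: floor(N/tau) >= m+2 requires it at N=%d",
            max_scale, reduced, n,
        )
        max_scale = reduced
    sd0 = float(np.std(x))  # population SD, ddof=0
    if sd0 == 0:
        # constant series: entropy is 0 at any positive tolerance
        sd0 = 1.0
    scales = np.arange(1, max_scale + 1)
    values = np.empty(max_scale, dtype=float)
    n_eff = n // scales
    for tau in scales:
        y = coarse_grain(x, int(tau))
        if params.r_mode == "fixed_original_sd":
            r_abs = params.r * sd0
        else:
            sd_t = float(np.std(y))
            r_abs = params.r * (sd_t if sd_t > 0 else 1.0)
        try:
            if kind == "MSE":
                values[tau - 1] = sample_entropy(y, params.m, r_abs)
            else:
                values[tau - 1] = fuzzy_entropy(y, params.m, r_abs, params.fuzzy_power)
        except DegenerateSignalError:
            # no resolvable template pairs at this scale: undefined, the
            # CAI over this curve will be reported missing
            logger.warning("%s undefined at scale %d (degenerate tolerance)",
                           kind, tau)
            values[tau - 1] = math.nan
    curve_cai = cai(values) if max_scale >= 2 else math.nan
    if not np.isfinite(curve_cai):
        logger.warning("%s CAI undefined: curve contains non-finite entropies", kind)
    return EntropyCurve(kind=kind, scales=scales, values=values,
                        cai=curve_cai, n_effective=n_eff)


def mse_curve(x, params: EntropyParams | None = None) -> EntropyCurve:
    """Multiscale (sample) entropy curve with its CAI."""
    return _curve(x, params or EntropyParams(), "MSE")


def mfe_curve(x, params: EntropyParams | None = None) -> EntropyCurve:
    """Multiscale fuzzy entropy curve with its CAI."""
    return _curve(x, params or EntropyParams(), "MFE")
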