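"""Core data containers: single-channel recordings and protocol epochs.

A recording session yields five synchronous channels per subject and
condition: tissue oxygen saturation (``oxy_sat``, percent), the three
speed-resolved perfusion components (``V1`` < 1 mm/s, ``V2`` 1-10 mm/s,
``V3`` > 10 mm/s, arbitrary perfusion units) and the probe temperature
set-point (``temperature``, deg C). Each channel is held as its own
:class:`SignalRecord`.

The measurement protocol is three back-to-back epochs — baseline,
stimulation, post — described by an :class:`EpochSpec` in seconds from
recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, RangeError

GROUPS = ("TS", "BC")
CONDITIONS = ("BC", "38", "40", "42", "44")
CHANNELS = ("oxy_sat", "V1", "V2", "V3", "temperature")
PERFUSION_CHANNELS = ("V1", "V2", "V3")
EPOCH_NAMES = ("baseline", "stimulation", "post")


@dataclass
class SignalRecord:
    """One subject/condition/channel time series sampled on a uniform grid.

    Parameters
    ----------
    subject_id : str
        Subject label, unique within its group.
    group : {"TS", "BC"}
        Thermal-stimulation or blank-control group.
    condition : {"BC", "38", "40", "42", "44"}
        Stimulation condition (probe set-point in deg C, or unheated control).
    channel : {"oxy_sat", "V1", "V2", "V3", "temperature"}
    sampling_rate_hz : float
        Samples per second (3 Hz for EPOS-style recordings).
    t0_s : float
        Time of the first sample, seconds.
    values : numpy.ndarray
        Finite sample values; oxy_sat is clipped to [0, 100] percent.
    """

    subject_id: str
    group: str
    condition: str
    channel: str
    sampling_rate_hz: float
    t0_s: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")
        if self.channel == "oxy_sat" and (
            self.values.size and (self.values.min() < 0 or self.values.max() > 100)
        ):
            raise ParameterError("oxy_sat values must lie in [0, 100] percent")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.condition, self.channel)

    def with_values(self, values: np.ndarray, t0_s: float | None = None) -> "SignalRecord":
        return replace(self, values=np.asarray(values, dtype=float),
                       t0_s=self.t0_s if t0_s is None else t0_s)


@dataclass(frozen=True)
class EpochSpec:
    """Half-open, contiguous protocol windows ``[start_s, end_s)``."""

    baseline: tuple[float, float]
    stimulation: tuple[float, float]
    post: tuple[float, float]

    def __post_init__(self):
        prev_end = None
        for name in EPOCH_NAMES:
            start, end = getattr(self, name)
            if not end > start:
                raise ParameterError(f"epoch {name} has non-positive length")
            if prev_end is not None and not np.isclose(start, prev_end):
                raise ParameterError("epochs must be contiguous and non-overlapping")
            prev_end = end

    @classmethod
    def from_minutes(cls, baseline: float = 30.0, stimulation: float = 30.0,
                     post: float = 30.0, t0_s: float = 0.0) -> "EpochSpec":
        b = t0_s + baseline * 60.0
        s = b + stimulation * 60.0
        p = s + post * 60.0
        return cls(baseline=(t0_s, b), stimulation=(b, s), post=(s, p))

    def window(self, which: str) -> tuple[float, float]:
        if which not in EPOCH_NAMES:
            raise ParameterError(f"unknown epoch {which!r}")
        return getattr(self, which)

    def after_window(self, mode: str = "stimulation") -> tuple[float, float]:
        """The 'after stimulation' analysis window.

        ``stimulation`` (default) uses the 30-min heating epoch, ``post``
        the recovery epoch, ``both`` their concatenation.
        """
        if mode == "stimulation":
            return self.stimulation
        if mode == "post":
            return self.post
        if mode == "both":
            return (self.stimulation[0], self.post[1])
        raise ParameterError(f"unknown after_window mode {mode!r}")

    @property
    def span(self) -> tuple[float, float]:
        return (self.baseline[0], self.post[1])
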