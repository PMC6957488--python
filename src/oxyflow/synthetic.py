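"""Synthetic EPOS-style cohort generator with known ground truth.

Emulates the study protocol — a 30-min baseline, a 30-min probe-heating
epoch at one of 38/40/42/44 deg C (or an unheated blank control), and a
30-min post epoch — at 3 Hz, producing per subject and condition five
synchronous channels: tissue oxygen saturation (percent), the three
speed-resolved perfusion components V1/V2/V3 (arbitrary units) and the
probe temperature set-point.

Ground truth the generator controls, and the analysis must recover:

* the temperature-dependent mean response (amplitude, time-to-peak,
  post-stimulation decay; the hottest condition does not decay),
* the signal complexity, via the white vs 1/f composition of the noise
  (per condition during stimulation/post),
* the rank correlation between each perfusion component and oxygen
  saturation, via Gaussian shared-noise mixing: a target Spearman rho_s is
  mapped to the Pearson weight 2*sin(pi*rho_s/6) (the exact bivariate
  Gaussian relation), and the perfusion channel mixes the *full* oxygen
  deviation (thermal trend + noise) with private same-spectrum noise, so
  the coupling governs the rank correlation even when the trend dominates
  and the coupling=1, fully-shared limit is exactly comonotone
  (pre-clipping).

All randomness flows from a single seed through per-(subject, condition)
numpy SeedSequences, so identical (design, config) reproduce identical
output bit-for-bit regardless of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, ParameterError
from .records import CONDITIONS, PERFUSION_CHANNELS, EpochSpec, SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "StudyDesign",
    "generate_noise",
    "response_curve",
    "generate_subject",
    "generate_cohort",
    "spearman_to_pearson",
]

TEMPERATURES = ("38", "40", "42", "44")


def _default_amplitude():
    return {"38": 6.0, "40": 10.0, "42": 16.0, "44": 20.0}


def _default_time_to_peak():
    return {"38": 1800.0, "40": 900.0, "42": 300.0, "44": 300.0}


def _default_decay():
    # hotter stimuli decay more slowly; no decay at 44 deg C
    return {"38": 1 / 600.0, "40": 1 / 1200.0, "42": 1 / 2400.0, "44": 0.0}


def _default_stim_white_fraction():
    # stimulation reduces complexity most at the mild temperatures
    # (white noise has the lower CAI over scales 1-20)
    return {"BC": 0.5, "38": 0.9, "40": 0.9, "42": 0.7, "44": 0.7}


def _default_coupling():
    # stimulation-epoch Spearman targets per (condition, channel):
    # mild heat tightens the perfusion-oxygenation association, strong
    # heat decouples it
    return {
        ("BC", "V1"): 0.3, ("BC", "V2"): 0.3, ("BC", "V3"): 0.3,
        ("38", "V1"): 0.6, ("38", "V2"): 0.55, ("38", "V3"): 0.55,
        ("40", "V1"): 0.25, ("40", "V2"): 0.3, ("40", "V3"): 0.6,
        ("42", "V1"): 0.0, ("42", "V2"): 0.05, ("42", "V3"): 0.2,
        ("44", "V1"): -0.1, ("44", "V2"): 0.0, ("44", "V3"): 0.2,
    }


def _default_baseline_coupling():
    return {"V1": 0.3, "V2": 0.3, "V3": 0.3}


def _default_perfusion_baseline():
    return {"V1": 20.0, "V2": 10.0, "V3": 5.0}


def _default_perfusion_gain():
    return {"V1": 0.8, "V2": 0.5, "V3": 0.3}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's documented study
    conditions (the protocol structure is fixed by the design, the numeric
    levels are free parameters)."""

    sampling_rate_hz: float = 3.0
    epoch_minutes: tuple[float, float, float] = (30.0, 30.0, 30.0)
    baseline_oxy_pct: float = 50.0
    response_amplitude_pct: dict = field(default_factory=_default_amplitude)
    time_to_peak_s: dict = field(default_factory=_default_time_to_peak)
    post_decay_rate_per_s: dict = field(default_factory=_default_decay)
    subject_baseline_sd_pct: float = 3.0   # between-subject baseline spread
    subject_amplitude_cv: float = 0.25     # between-subject response spread
    white_fraction: float = 0.5            # baseline-epoch noise mix
    stim_white_fraction: dict = field(default_factory=_default_stim_white_fraction)
    white_fraction_jitter: float = 0.0     # per-subject uniform jitter half-width
    complexity_linked: bool = True         # V channels share the subject's mix
    noise_sd: float = 2.0                  # oxygen-saturation noise SD, percent
    coupling: dict = field(default_factory=_default_coupling)
    baseline_coupling: dict = field(default_factory=_default_baseline_coupling)
    perfusion_baseline: dict = field(default_factory=_default_perfusion_baseline)
    perfusion_gain: dict = field(default_factory=_default_perfusion_gain)
    probe_off_temp_c: float = 32.0
    seed: int = 0

    def __post_init__(self):
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if not (0 < self.baseline_oxy_pct < 100):
            raise ParameterError("baseline_oxy_pct must be in (0, 100)")
        if not (0 <= self.white_fraction <= 1):
            raise ParameterError("white_fraction must be in [0, 1]")
        for w in self.stim_white_fraction.values():
            if not (0 <= w <= 1):
                raise ParameterError("stim_white_fraction values must be in [0, 1]")
        if not self.noise_sd > 0:
            raise ParameterError("noise_sd must be positive")
        for c in list(self.coupling.values()) + list(self.baseline_coupling.values()):
            if not (-1 <= c <= 1):
                raise ParameterError("coupling values must be in [-1, 1]")
        for minutes in self.epoch_minutes:
            n = minutes * 60.0 * self.sampling_rate_hz
            if not (abs(n - round(n)) < 1e-9 and round(n) >= 2):
                raise ParameterError(
                    "each epoch must contain an integer number (>= 2) of samples")

    @property
    def epoch_spec(self) -> EpochSpec:
        b, s, p = self.epoch_minutes
        return EpochSpec.from_minutes(b, s, p)

    @property
    def samples_per_epoch(self) -> tuple[int, int, int]:
        return tuple(int(round(m * 60.0 * self.sampling_rate_hz))
                     for m in self.epoch_minutes)


@dataclass
class StudyDesign:
    """Cohort layout: a thermal-stimulation (TS) group recorded once per
    temperature, in a per-subject random order, and a blank-control (BC)
    group recorded once."""

    ts_subjects: int = 29
    bc_subjects: int = 30
    conditions: tuple = CONDITIONS
    seed: int = 0
    stimulation_order: dict = field(init=False)

    def __post_init__(self):
        if self.ts_subjects < 1 or self.bc_subjects < 1:
            raise ParameterError("subject counts must be positive")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        self.stimulation_order = {
            f"TS{i + 1:02d}": tuple(rng.permutation(TEMPERATURES))
            for i in range(self.ts_subjects)
        }

    @property
    def ts_ids(self) -> list[str]:
        return list(self.stimulation_order)

    @property
    def bc_ids(self) -> list[str]:
        return [f"BC{i + 1:02d}" for i in range(self.bc_subjects)]

    def recordings(self) -> list[tuple[str, str, str]]:
        """All (subject_id, group, condition) recordings in the design."""
        out = [(s, "BC", "BC") for s in self.bc_ids]
        for s in self.ts_ids:
            out.extend((s, "TS", t) for t in self.stimulation_order[s])
        return out


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman
    correlation is ``rho_s`` (rho_p = 2 sin(pi rho_s / 6))."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_noise(n_samples: int, white_fraction: float, sd: float, seed) -> np.ndarray:
    """Zero-mean mixture w*white + (1-w)*pink noise, rescaled so the
    sample SD is exactly ``sd``.

    Pink (1/f) noise is synthesized by spectral shaping: white Gaussian
    noise is filtered in the Fourier domain with a 1/sqrt(f) amplitude
    envelope (DC removed). ``seed`` may be an int, a SeedSequence or a
    Generator.
    """
    if not (isinstance(n_samples, (int, np.integer)) and n_samples >= 2):
        raise ParameterError("n_samples must be an integer >= 2")
    for name, v in (("white_fraction", white_fraction), ("sd", sd)):
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite")
    if not (0 <= white_fraction <= 1):
        raise ParameterError("white_fraction must be in [0, 1]")
    if not sd > 0:
        raise ParameterError("sd must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    pink = _pink_noise(n_samples, rng)
    white = white - white.mean()
    w_sd = white.std()
    p_sd = pink.std()
    if w_sd > 0:
        white /= w_sd
    if p_sd > 0:
        pink /= p_sd
    y = white_fraction * white + (1.0 - white_fraction) * pink
    y = y - y.mean()
    y_sd = y.std()
    if y_sd == 0:
        raise ParameterError("degenerate noise mixture")
    return y * (sd / y_sd)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = 1.0 / np.sqrt(f[1:])
    y = np.fft.irfft(spec * amp, n)
    return y - y.mean()


def response_curve(condition: str, t: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Deterministic mean oxygen-saturation trajectory (percent).

    Flat at baseline level; saturating exponential rise during
    stimulation with time constant time_to_peak/3 (so ~95% of the
    amplitude is reached at the nominal time-to-peak, capped at the epoch
    end); exponential decay at the configured rate afterwards. The blank
    control is flat throughout.
    """
    if condition not in config_conditions(config):
        raise ParameterError(f"unknown condition {condition!r}")
    t = np.asarray(t, dtype=float)
    base = config.baseline_oxy_pct
    if condition == "BC":
        return np.full(t.shape, base)
    b_min, s_min, _ = config.epoch_minutes
    t1 = b_min * 60.0
    t2 = t1 + s_min * 60.0
    amp = float(config.response_amplitude_pct[condition])
    tau = float(config.time_to_peak_s[condition]) / 3.0
    k = float(config.post_decay_rate_per_s[condition])
    out = np.full(t.shape, base)
    stim = (t >= t1) & (t < t2)
    out[stim] = base + amp * (1.0 - np.exp(-(t[stim] - t1) / tau))
    end_level = amp * (1.0 - np.exp(-(t2 - t1) / tau))
    post = t >= t2
    out[post] = base + end_level * np.exp(-k * (t[post] - t2))
    return out


def config_conditions(config: SyntheticConfig) -> tuple:
    return ("BC",) + tuple(config.response_amplitude_pct)


def _subject_rng(config_seed: int, group: str, subject_index: int,
                 condition: str) -> np.random.Generator:
    gcode = 0 if group == "BC" else 1
    ccode = CONDITIONS.index(condition)
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, gcode, subject_index, ccode]))


def _epoch_white_fractions(config: SyntheticConfig, condition: str,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch white fractions for the oxygen channel and for private
    perfusion noise (possibly decoupled)."""
    wf_stim = config.stim_white_fraction.get(condition, config.white_fraction)
    base = np.array([config.white_fraction, wf_stim, wf_stim])
    j = config.white_fraction_jitter
    if j > 0:
        oxy = np.clip(base + j * rng.uniform(-1, 1), 0.0, 1.0)
        if config.complexity_linked:
            priv = oxy
        else:
            priv = np.clip(base + j * rng.uniform(-1, 1), 0.0, 1.0)
    else:
        oxy = base
        priv = base
    return oxy, priv


def generate_subject(subject_id: str, condition: str, design: StudyDesign,
                     config: SyntheticConfig) -> list[SignalRecord]:
    """Generate the five channels of one subject/condition recording."""
    if condition not in design.conditions:
        raise DesignError(f"condition {condition!r} not in the design")
    if subject_id in design.stimulation_order:
        group, idx = "TS", design.ts_ids.index(subject_id)
        if condition == "BC":
            raise DesignError(f"TS subject {subject_id!r} has no BC recording")
    elif subject_id in design.bc_ids:
        group, idx = "BC", design.bc_ids.index(subject_id)
        if condition != "BC":
            raise DesignError(f"BC subject {subject_id!r} is never stimulated")
    else:
        raise DesignError(f"subject {subject_id!r} not in the design")

    rng = _subject_rng(config.seed, group, idx, condition)
    fs = config.sampling_rate_hz
    n_per_epoch = config.samples_per_epoch
    n_total = sum(n_per_epoch)
    t = np.arange(n_total) / fs

    # between-subject variability: each subject has their own resting
    # level and response gain around the condition template
    offset = config.subject_baseline_sd_pct * rng.standard_normal()
    amp_mult = max(0.0, 1.0 + config.subject_amplitude_cv * rng.standard_normal())
    base_subject = config.baseline_oxy_pct + offset
    resp = base_subject + amp_mult * (
        response_curve(condition, t, config) - config.baseline_oxy_pct)
    wf_oxy, wf_priv = _epoch_white_fractions(config, condition, rng)

    # per-epoch noise streams: the oxygen noise is the shared latent
    oxy_noise = np.concatenate([
        generate_noise(n, wf, 1.0, rng) for n, wf in zip(n_per_epoch, wf_oxy)])
    epoch_slices = []
    start = 0
    for n in n_per_epoch:
        epoch_slices.append(slice(start, start + n))
        start += n

    oxy_vals = resp + config.noise_sd * oxy_noise
    n_clipped = int(np.sum((oxy_vals < 0) | (oxy_vals > 100)))
    if n_clipped:
        logger.warning("subject %s/%s: clipped %d oxygen-saturation samples",
                       subject_id, condition, n_clipped)
    oxy_vals = np.clip(oxy_vals, 0.0, 100.0)

    meta = dict(subject_id=subject_id, group=group, condition=condition,
                sampling_rate_hz=fs, t0_s=0.0)
    records = [SignalRecord(channel="oxy_sat", values=oxy_vals, **meta)]

    # perfusion channels: epoch-wise mixture of the full oxygen deviation
    # (trend + noise, the shared latent) and private same-spectrum noise.
    # Mixing the *whole* deviation, not just the noise, keeps the
    # configured coupling in charge of the rank correlation even when the
    # thermal trend dominates the within-epoch variance; the coupling=1,
    # fully-shared limit is an exact affine image of the oxygen signal.
    shared = (resp - base_subject) + config.noise_sd * oxy_noise
    for chan in PERFUSION_CHANNELS:
        rho_targets = [config.baseline_coupling.get(chan, 0.0),
                       config.coupling.get((condition, chan), 0.0)]
        rho_targets.append(rho_targets[1])  # post epoch follows stimulation
        mixed = np.empty(n_total)
        for sl, n_e, rho_s, wf in zip(epoch_slices, n_per_epoch, rho_targets, wf_priv):
            rho_p = spearman_to_pearson(rho_s)
            private = generate_noise(n_e, wf, 1.0, rng)
            sd_e = shared[sl].std()
            mixed[sl] = (rho_p * shared[sl]
                         + np.sqrt(max(0.0, 1 - rho_p ** 2)) * sd_e * private)
        vals = config.perfusion_baseline[chan] + config.perfusion_gain[chan] * mixed
        records.append(SignalRecord(channel=chan, values=vals, **meta))

    # programmed probe set-point trace
    temp = np.full(n_total, config.probe_off_temp_c)
    if condition != "BC":
        temp[epoch_slices[1]] = float(condition)
    records.append(SignalRecord(channel="temperature", values=temp, **meta))
    return records


def generate_cohort(design: StudyDesign, config: SyntheticConfig) -> list[SignalRecord]:
    """Generate every recording in the design (5 channels each)."""
    records = []
    for subject_id, _group, condition in design.recordings():
        records.extend(generate_subject(subject_id, condition, design, config))
    return records
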