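# Methods

## Signals and protocol

A recording is one subject × condition session of five synchronous
channels sampled at 3 Hz: tissue oxygen saturation (percent; the
microvascular value measured by diffuse reflectance spectroscopy, not
arterial SpO₂), speed-resolved perfusion V1/V2/V3 (arbitrary perfusion
units; speed bands < 1, 1–10, > 10 mm/s) and the probe temperature
set-point. The protocol is three contiguous half-open epochs —
baseline [0, 1800) s, stimulation [1800, 3600) s, post [3600, 5400) s —
giving exactly 5,400 samples per epoch. The study design is a
thermal-stimulation group (29 subjects, one session per temperature
38/40/42/44 °C, order randomized per subject) and a blank-control group
(30 subjects, unheated), i.e. 146 recordings and five condition groups.

"Before stimulation" always means the baseline epoch. "After
stimulation" defaults to the stimulation epoch, because the condition
effects are maximal while the probe is heated; the post epoch, or the
concatenation of both, can be selected instead (`after_window`). Which
window was used is recorded in every output table.

## Multiscale entropy and the CAI

Coarse-graining at scale τ replaces the series by non-overlapping block
means (length ⌊N/τ⌋, tail discarded). At each scale:

* **SampEn(m, r_abs)** = −ln(A/B). Templates of length m are taken at
  positions 1…N−m (the same index range as the m+1 templates), distance
  is Chebyshev, matching is *strict* (< r_abs), self-matches are
  excluded; B counts m-matches, A the subset that still match at length
  m+1. A = 0 returns +inf — an undefined sentinel, not a ceiling value.
  B = 0 raises a degeneracy error (and is recorded as NaN inside a curve).
* **FuzzyEn(m, r_abs, n)** = ln φ_m − ln φ_{m+1}, where each template has
  its own mean subtracted and φ_ℓ is the mean of exp(−(d/r_abs)^n) over
  ordered pairs i ≠ j.

Defaults are m = 2, r = 0.15, fuzzy power n = 2, and max_scale = 20. The
absolute tolerance is r × population SD (ddof = 0) of the *original*
series, reused unchanged at every scale (the convention of the classic
multiscale-entropy literature); per-scale re-normalisation is available
(`r_mode="per_scale_sd"`) but not default. The population/sample SD
distinction is immaterial at N ≈ 5,400 but fixed for determinism. When
⌊N/max_scale⌋ < m + 2 the scale range is reduced automatically with a
logged warning.

The **CAI** is the trapezoidal integral of the entropy-versus-scale curve
with unit scale spacing (a flat curve of height h over scales 1…21 gives
20·h). If any scale is undefined (+inf or NaN) the CAI is reported
missing rather than interpolated or capped: substituting a ceiling value
would silently bias group means toward whatever cap was chosen.

The inner template-matching loops are O(N²) and JIT-compiled with numba;
at N = 16,200 a scale-1 SampEn takes ~0.6 s on one core. Brute-force
reference implementations live in the test suite and the two paths are
required to agree to 1e-10 on hundreds of short random series.

## Correlations

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks for
ties). The two-sided p uses the large-sample t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df; for n ≤ 10 an exact permutation p (full
enumeration of one ranking's permutations) is available. Constant inputs
have undefined ρ and are flagged, not silently dropped.

Time-domain correlations are computed per subject on the raw 3 Hz epoch
samples by default (the minute-mean alternative is a switch and is
recorded in outputs). Cross-subject CAI correlations drop incomplete
pairs pairwise and report the effective n; fewer than three complete
pairs is an error. p-values are per-pair; no multiplicity correction is
applied to these descriptive correlation panels.

## Group comparisons

The omnibus test is the classical one-way independent-design F across the
five condition groups — with the full design, df (4, 141). (A mixed
repeated-measures formulation would need a covariance structure the
one-way df pattern does not reflect; repeated-measures machinery is
deliberately out of scope.) Posttests are label-shuffling permutation
tests on the difference of group means: two-sided, add-one corrected,
p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_perm), with exhaustive
enumeration when the pooled sample is ≤ 10. The permutation stream is
seeded per pair from a single run seed, and the internal group order is
canonicalized so swapping the two groups flips the statistic's sign but
reproduces the identical p. Default n_perm = 10,000; significance
α = 0.05 two-sided, no multiplicity correction by default (a Holm option
exists behind a flag) since the design reports per-cell significance.

## Synthetic generator

The generator's purpose is recoverable ground truth, not biophysical
fidelity. Its defaults define the package's study conditions:

| parameter | default | why |
|---|---|---|
| baseline oxygen saturation | 50 % | mid-range microvascular value; the magnitude is a free parameter of the generator |
| between-subject baseline SD | 3 % | gives realistic within-group spread so group F statistics are finite and moderate |
| response amplitude (38/40/42/44 °C) | 6/10/16/20 % | monotone in temperature |
| time-to-peak (s) | 1800/900/300/300 | slow rise at 38 °C, maximal within ~5 min at 42–44 °C |
| post decay rate (s⁻¹) | 1/600, 1/1200, 1/2400, 0 | slower decay at hotter stimuli; no decay at 44 °C |
| between-subject amplitude CV | 0.25 | response heterogeneity |
| noise SD | 2 % | visible but not dominating the thermal response |
| baseline white fraction | 0.5 | mixed-complexity resting signal |
| stimulation white fraction | BC .5, 38 .9, 40 .9, 42 .7, 44 .7 | complexity reduced most by mild heating, partially restored at higher temperatures (white noise has the lower CAI over scales 1–20) |
| stimulation couplings (V1) | BC .3, 38 .6, 40 .25, 42 0, 44 −.1 | association tightened by mild heat, abolished/reversed by strong heat |

The mean response is a saturating exponential rise (time constant =
time-to-peak/3, so ~95 % of the amplitude is reached at the nominal
time-to-peak) followed by exponential decay; the blank control is flat.
The physiological axon-reflex/plateau biphasic shape is deliberately not
modelled — the analysis treats the stimulation epoch as a whole.

Noise is w·white + (1−w)·(1/f), each component unit-SD, the mixture
rescaled to the requested SD exactly. 1/f noise is synthesized by
spectral shaping (FFT of white noise, 1/√f amplitude envelope, DC
removed) — exact seeding and a flat, transparent implementation;
autoregressive cascades were rejected as opaque. Noise is generated per
epoch so the stimulation epoch can carry its own complexity; entropy is
always computed within epochs, so the epoch-boundary discontinuity in
noise character is never inside an analysis window.

Coupling: a Spearman target ρ_s is mapped to a Pearson weight
ρ_p = 2·sin(πρ_s/6) (exact for bivariate Gaussians; ±1 → ±1, 0 → 0,
0.6 → 0.618). Each perfusion channel mixes the **full oxygen deviation**
(thermal trend + noise, per epoch, variance-matched) with private
same-spectrum noise at weights (ρ_p, √(1−ρ_p²)). Mixing the whole
deviation rather than only the noise keeps the configured coupling in
charge of the rank correlation even when the deterministic trend
dominates the within-epoch variance; the ρ_s = 1 fully-shared limit is an
exact affine image of the oxygen signal (ρ = 1 before clipping). Because
the trend is not Gaussian, the empirical Spearman ρ tracks the target
approximately (e.g. −0.25 recovered for a −0.3 target at 44 °C) and
monotonically — sufficient for ordering-recovery validation, and the
reason validation asserts orderings rather than point values.

Oxygen saturation is clipped to [0, 100] after noise addition; clip
events are logged because clipping flattens segments and distorts
entropy. With the default levels clipping is never triggered.

Per-subject complexity heterogeneity (`white_fraction_jitter`) supports
the CAI-correlation validation: when `complexity_linked` is true the
perfusion channels share the subject's noise mix (CAIs correlate across
subjects); when false they draw independent mixes (null).

All randomness derives from one seed through per-(subject, condition)
`SeedSequence`s, so cohorts are bit-for-bit reproducible regardless of
generation order.

### What the generator does not emulate

Instrument physics (DRS spectra, the Monte-Carlo speed decomposition),
cardiac/respiratory oscillatory bands, movement artefacts, non-Gaussian
noise, and the biphasic thermal response. Passing validation therefore
shows the *pipeline* is correct and calibrated under controlled
conditions; it does not certify conclusions about human data.

## Validation experiments and problem sizes

`oxyflow.validation` packages the seeded studies used by the test suite
and the acceptance script, at sizes chosen to balance statistical power
against a single-core run of a few minutes:

* iid-Gaussian SampEn vs the analytic value −ln(2Φ(r/√2)−1): N = 5,000,
  20 seeds (observed |error| ~ 0.001–0.005, tolerance 0.05).
* white vs 1/f MSE contrast: N = 16,200 (one full epoch-triplet length),
  scales 1–20, 20 replicates.
* permutation type-I error: 1,000 null replicates, n = 15 per group,
  n_perm = 999.
* coupling-ordering recovery and the pre-stimulation CAI null: 10-per-
  group cohorts at full 30-min epochs, 10 seeds each.

Pipeline-level tests use 2-minute epochs and 4-per-group cohorts: every
contract (epoch bookkeeping, determinism, table schemas) is length-
invariant, and entropy-based group effects are validated separately at
full length.

## Known limitations

* The empirical Spearman coupling is exact only in the Gaussian (trend-
  free) regime; under strong trends it is a monotone approximation of the
  target.
* The one-way F ignores the repeated-measures structure of the
  thermal-stimulation group (each TS subject contributes four
  recordings); this matches the (4, 141) df convention but understates
  within-subject correlation.
* Undefined entropies at large scales (short coarse-grained series with
  no template matches) propagate to missing CAIs; cohort analyses drop
  those subjects pairwise, which can shrink n in high-complexity
  conditions.
* The MATLAB export reader handles numeric vectors under a user-supplied
  name map only; the long CSV is the canonical interchange format.
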