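"""Self-validation experiments: seeded simulation studies that check the
package's statistics against analytic limits and against the generator's
ground truth.

Each function runs a complete, reproducible experiment and returns a plain
dict of summary numbers. They are used by the test suite and by the
repository's acceptance script; they are also a convenient way to sanity-
check an installation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .association import timecourse_correlations
from .entropy import EntropyParams, mse_curve, sample_entropy
from .group_stats import oneway_anova, permutation_pairwise
from .pipeline import compute_cai_table
from .records import PERFUSION_CHANNELS
from .synthetic import StudyDesign, SyntheticConfig, generate_noise, generate_subject

__all__ = [
    "gaussian_sampen_limit",
    "mse_noise_contrast",
    "permutation_type1_rate",
    "coupling_ordering_recovery",
    "baseline_cai_null_rate",
]


def _child_seed(seed: int, *key: int) -> int:
    """Derive a bounded child seed (< 2^31) from a base seed and a key."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2 ** 31))


def gaussian_sampen_limit(n: int = 5000, m: int = 2, r: float = 0.15,
                          n_seeds: int = 20, seed: int = 0) -> dict:
    """Scale-1 SampEn of iid Gaussian noise versus its analytic value.

    For an iid series the probability that two independent samples lie
    within r*sigma is 2*Phi(r/sqrt(2)) - 1, and SampEn converges to the
    negative log of that matching probability.
    """
    analytic = -np.log(2 * sps.norm.cdf(r / np.sqrt(2)) - 1)
    values = []
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101, k]))
        x = rng.standard_normal(n)
        values.append(sample_entropy(x, m, r * x.std()))
    return {"mean": float(np.mean(values)), "analytic": float(analytic),
            "abs_error": float(abs(np.mean(values) - analytic)),
            "n": n, "n_seeds": n_seeds}


def mse_noise_contrast(n: int = 16_200, max_scale: int = 20,
                       n_seeds: int = 20, seed: int = 0) -> dict:
    """The classic multiscale contrast between white and 1/f noise.

    At matched SD, white noise loses entropy under coarse-graining
    (decreasing MSE curve) while 1/f noise does not, so the 1/f CAI over
    scales 1..max_scale exceeds the white-noise CAI.
    """
    params = EntropyParams(max_scale=max_scale)
    pink_wins = 0
    cai_white, cai_pink = [], []
    white_scales, white_values = [], []
    for k in range(n_seeds):
        white = generate_noise(n, 1.0, 1.0, seed=np.random.SeedSequence([seed, 201, k]))
        pink = generate_noise(n, 0.0, 1.0, seed=np.random.SeedSequence([seed, 202, k]))
        cw = mse_curve(white, params)
        cp = mse_curve(pink, params)
        cai_white.append(cw.cai)
        cai_pink.append(cp.cai)
        pink_wins += cp.cai > cw.cai
        white_scales.extend(cw.scales.tolist())
        white_values.extend(cw.values.tolist())
    trend_rho, trend_p = sps.spearmanr(white_scales, white_values)
    return {"pink_wins": int(pink_wins), "n_seeds": n_seeds,
            "mean_cai_white": float(np.mean(cai_white)),
            "mean_cai_pink": float(np.mean(cai_pink)),
            "white_trend_rho": float(trend_rho),
            "white_trend_p": float(trend_p), "n": n}


def permutation_type1_rate(n_reps: int = 1000, n_per_group: int = 15,
                           n_perm: int = 999, alpha: float = 0.05,
                           seed: int = 0) -> dict:
    """Empirical type-I error of the permutation posttest under the null
    (both groups iid standard normal)."""
    rejections = 0
    for k in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 301, k]))
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        res = permutation_pairwise(a, b, n_perm=n_perm,
                                   seed=_child_seed(seed, 302, k))
        rejections += res.p < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha,
            "n_perm": n_perm}


def coupling_ordering_recovery(n_seeds: int = 10, subjects_per_group: int = 10,
                               seed: int = 0,
                               epoch_minutes=(30.0, 30.0, 30.0)) -> dict:
    """Recovery of the configured coupling ordering 38 > BC > 44.

    Cohorts are generated with stimulation-epoch Spearman targets 0.6 at
    38 deg C, 0 in the blank control and -0.3 at 44 deg C; per seed the
    group-mean time-domain rho (V1 vs oxygen, stimulation epoch) must
    reproduce that ordering.
    """
    coupling = {}
    for ch in PERFUSION_CHANNELS:
        coupling[("38", ch)] = 0.6
        coupling[("BC", ch)] = 0.0
        coupling[("44", ch)] = -0.3
    successes = 0
    mean_rhos = {"38": [], "BC": [], "44": []}
    for k in range(n_seeds):
        config = SyntheticConfig(
            epoch_minutes=tuple(epoch_minutes), coupling=coupling,
            baseline_coupling={ch: 0.0 for ch in PERFUSION_CHANNELS},
            seed=_child_seed(seed, 401, k))
        design = StudyDesign(ts_subjects=subjects_per_group,
                             bc_subjects=subjects_per_group,
                             seed=_child_seed(seed, 402, k))
        records = []
        for sid in design.bc_ids:
            records.extend(generate_subject(sid, "BC", design, config))
        for sid in design.ts_ids:
            for cond in ("38", "44"):
                records.extend(generate_subject(sid, cond, design, config))
        df = timecourse_correlations(records, config.epoch_spec,
                                     epoch="stimulation",
                                     pairs=(("V1", "oxy_sat"),))
        by_cond = df.groupby("condition")["rho"].mean()
        successes += by_cond["38"] > by_cond["BC"] > by_cond["44"]
        for cond in mean_rhos:
            mean_rhos[cond].append(float(by_cond[cond]))
    return {"successes": int(successes), "n_seeds": n_seeds,
            "mean_rho_38": float(np.mean(mean_rhos["38"])),
            "mean_rho_bc": float(np.mean(mean_rhos["BC"])),
            "mean_rho_44": float(np.mean(mean_rhos["44"]))}


def baseline_cai_null_rate(n_runs: int = 10, subjects_per_group: int = 10,
                           n_perm: int = 999, alpha: float = 0.05,
                           seed: int = 0,
                           epoch_minutes=(30.0, 30.0, 30.0),
                           max_scale: int = 20) -> dict:
    """Pre-stimulation null: the baseline-epoch MSE-CAI omnibus F across
    the five condition groups should be non-significant in most runs,
    because every condition shares one generator before stimulation."""
    nonsig = 0
    pvalues = []
    for k in range(n_runs):
        config = SyntheticConfig(epoch_minutes=tuple(epoch_minutes),
                                 seed=_child_seed(seed, 501, k))
        design = StudyDesign(ts_subjects=subjects_per_group,
                             bc_subjects=subjects_per_group,
                             seed=_child_seed(seed, 502, k))
        records = []
        for sid in design.bc_ids:
            records.extend(generate_subject(sid, "BC", design, config))
        for sid in design.ts_ids:
            for cond in ("38", "40", "42", "44"):
                records.extend(generate_subject(sid, cond, design, config))
        spec = config.epoch_spec
        tables = compute_cai_table(records, spec,
                                   {"baseline": spec.window("baseline")},
                                   EntropyParams(max_scale=max_scale),
                                   kinds=("MSE",), channels=("oxy_sat",))
        df = tables["cai"].dropna(subset=["cai"])
        groups = [df[df["condition"] == c]["cai"].to_numpy()
                  for c in ("BC", "38", "40", "42", "44")]
        res = oneway_anova(groups)
        pvalues.append(res.p)
        nonsig += res.p >= alpha
    return {"nonsignificant": int(nonsig), "n_runs": n_runs,
            "pvalues": [float(p) for p in pvalues]}
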