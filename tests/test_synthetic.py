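"""Synthetic cohort generator: protocol structure, noise control, coupling."""

import numpy as np
import pytest

from oxyflow import (
    DesignError,
    EntropyParams,
    ParameterError,
    StudyDesign,
    SyntheticConfig,
    generate_cohort,
    generate_noise,
    generate_subject,
    mse_curve,
    response_curve,
    spearman,
    spearman_to_pearson,
)
from oxyflow.records import PERFUSION_CHANNELS
from oxyflow.signal_io import extract_epoch


class TestGenerateNoise:
    def test_deterministic(self):
        a = generate_noise(500, 0.3, 1.5, seed=42)
        b = generate_noise(500, 0.3, 1.5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_sd_rescaled_exactly(self):
        y = generate_noise(1000, 0.0, 2.0, seed=1)
        assert y.std() == pytest.approx(2.0, abs=1e-9)
        assert y.mean() == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_uncorrelated_at_lag_one(self):
        n = 10_000
        y = generate_noise(n, 1.0, 1.0, seed=2)
        r1 = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(n)

    def test_pink_noise_positively_autocorrelated(self):
        y = generate_noise(10_000, 0.0, 1.0, seed=3)
        assert np.corrcoef(y[:-1], y[1:])[0, 1] > 0.3

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            generate_noise(1, 0.5, 1.0, seed=0)
        with pytest.raises(ParameterError):
            generate_noise(100, 1.5, 1.0, seed=0)
        with pytest.raises(ParameterError):
            generate_noise(100, 0.5, np.nan, seed=0)


class TestResponseCurve:
    def setup_method(self):
        self.config = SyntheticConfig()
        self.t = np.arange(0, 5400, 1 / 3)

    def test_blank_control_is_flat(self):
        y = response_curve("BC", self.t, self.config)
        np.testing.assert_array_equal(y, np.full_like(self.t, 50.0))

    def test_zero_amplitude_is_flat(self):
        cfg = SyntheticConfig(response_amplitude_pct={"38": 0.0, "40": 10.0,
                                                      "42": 16.0, "44": 20.0})
        y = response_curve("38", self.t, cfg)
        np.testing.assert_allclose(y, 50.0)

    def test_no_decay_at_hottest_condition(self):
        # default decay rate at 44 deg C is zero: post epoch holds the
        # stimulation-end level
        y = response_curve("44", self.t, self.config)
        post = y[self.t >= 3600]
        np.testing.assert_allclose(post, post[0])
        assert post[0] > 50.0

    def test_decay_at_milder_conditions(self):
        y = response_curve("38", self.t, self.config)
        post = y[self.t >= 3600]
        assert post[-1] < post[0]

    def test_rise_is_monotone_saturating(self):
        y = response_curve("42", self.t, self.config)
        stim = y[(self.t >= 1800) & (self.t < 3600)]
        assert np.all(np.diff(stim) >= 0)
        amp = self.config.response_amplitude_pct["42"]
        assert stim[-1] == pytest.approx(50.0 + amp, rel=0.01)

    def test_unknown_condition(self):
        with pytest.raises(ParameterError):
            response_curve("39", self.t, self.config)


class TestGenerateSubject:
    def test_default_protocol_sample_counts(self):
        design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=0)
        config = SyntheticConfig(seed=0)
        recs = generate_subject("TS01", "40", design, config)
        assert len(recs) == 5
        for rec in recs:
            assert rec.n_samples == 16_200  # 3 Hz x 90 min
        epoch = extract_epoch(recs[0], config.epoch_spec, "baseline")
        assert epoch.n_samples == 5_400

    def test_comonotone_limit(self, mini_spec):
        design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=1)
        coupling = {(c, ch): 1.0 for c in ("BC", "38", "40", "42", "44")
                    for ch in PERFUSION_CHANNELS}
        config = SyntheticConfig(epoch_minutes=(2, 2, 2), coupling=coupling,
                                 seed=1)
        recs = {r.channel: r for r in generate_subject("TS01", "38", design, config)}
        v1 = extract_epoch(recs["V1"], mini_spec, "stimulation").values
        oxy = extract_epoch(recs["oxy_sat"], mini_spec, "stimulation").values
        assert spearman(v1, oxy).rho > 0.99

    def test_null_coupling_near_zero(self, mini_spec):
        rhos = []
        for seed in range(8):
            design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=seed)
            config = SyntheticConfig(
                epoch_minutes=(2, 2, 2), seed=seed,
                coupling={(c, ch): 0.0 for c in ("BC", "38", "40", "42", "44")
                          for ch in PERFUSION_CHANNELS},
                baseline_coupling={ch: 0.0 for ch in PERFUSION_CHANNELS})
            recs = {r.channel: r for r in generate_subject("BC01", "BC",
                                                           design, config)}
            v1 = extract_epoch(recs["V1"], mini_spec, "stimulation").values
            oxy = extract_epoch(recs["oxy_sat"], mini_spec, "stimulation").values
            rhos.append(spearman(v1, oxy).rho)
        n = 360
        assert abs(np.mean(rhos)) < 4 / np.sqrt(n)

    def test_coupling_recovery_is_monotone(self):
        # mean empirical rho over replicates is monotone in the target
        grid = (-0.8, 0.0, 0.4, 0.8)
        means = []
        for target in grid:
            rhos = []
            for seed in range(20):
                design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=seed)
                config = SyntheticConfig(
                    epoch_minutes=(1, 1, 1), seed=seed,
                    coupling={("38", ch): target for ch in PERFUSION_CHANNELS},
                    baseline_coupling={ch: 0.0 for ch in PERFUSION_CHANNELS})
                recs = {r.channel: r for r in generate_subject(
                    "TS01", "38", design, config)}
                spec = config.epoch_spec
                v1 = extract_epoch(recs["V1"], spec, "stimulation").values
                oxy = extract_epoch(recs["oxy_sat"], spec, "stimulation").values
                rhos.append(spearman(v1, oxy).rho)
            means.append(np.mean(rhos))
        assert means == sorted(means)

    def test_design_mismatch_errors(self):
        design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=0)
        config = SyntheticConfig(epoch_minutes=(1, 1, 1), seed=0)
        with pytest.raises(DesignError):
            generate_subject("TS01", "BC", design, config)
        with pytest.raises(DesignError):
            generate_subject("BC01", "40", design, config)
        with pytest.raises(DesignError):
            generate_subject("XX99", "40", design, config)

    def test_temperature_trace_is_programmed_setpoint(self, mini_cohort,
                                                      mini_spec):
        recs = [r for r in mini_cohort
                if r.channel == "temperature" and r.condition == "42"]
        rec = recs[0]
        stim = extract_epoch(rec, mini_spec, "stimulation")
        base = extract_epoch(rec, mini_spec, "baseline")
        assert set(stim.values) == {42.0}
        assert set(base.values) == {32.0}


class TestStudyDesign:
    def test_every_recording_present(self):
        design = StudyDesign(ts_subjects=3, bc_subjects=2, seed=5)
        recs = design.recordings()
        assert len(recs) == 2 + 3 * 4
        for s in design.ts_ids:
            assert sorted(design.stimulation_order[s]) == ["38", "40", "42", "44"]

    def test_orders_are_seeded_permutations(self):
        a = StudyDesign(ts_subjects=5, bc_subjects=1, seed=9)
        b = StudyDesign(ts_subjects=5, bc_subjects=1, seed=9)
        assert a.stimulation_order == b.stimulation_order
        c = StudyDesign(ts_subjects=5, bc_subjects=1, seed=10)
        assert a.stimulation_order != c.stimulation_order


class TestCohort:
    def test_byte_identical_reproduction(self, mini_config):
        design = StudyDesign(ts_subjects=2, bc_subjects=2, seed=11)
        a = generate_cohort(design, mini_config)
        b = generate_cohort(design, mini_config)
        assert len(a) == len(b) == (2 + 2 * 4) * 5
        for ra, rb in zip(a, b):
            assert ra.key() == rb.key()
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_complexity_contrast_white_vs_pink(self):
        # scale-1 SampEn higher for white, CAI higher for 1/f, per the
        # classic multiscale contrast, via the entropy module itself
        params = EntropyParams(max_scale=10)
        s1_white, s1_pink, cai_white, cai_pink = [], [], [], []
        for seed in range(3):
            w = generate_noise(4096, 1.0, 1.0, seed=(seed, 0))
            p = generate_noise(4096, 0.0, 1.0, seed=(seed, 1))
            cw, cp = mse_curve(w, params), mse_curve(p, params)
            s1_white.append(cw.values[0])
            s1_pink.append(cp.values[0])
            cai_white.append(cw.cai)
            cai_pink.append(cp.cai)
        assert np.mean(s1_white) > np.mean(s1_pink)
        assert np.mean(cai_pink) > np.mean(cai_white)


def test_spearman_to_pearson_endpoints():
    assert spearman_to_pearson(0.0) == 0.0
    assert spearman_to_pearson(1.0) == pytest.approx(1.0)
    assert spearman_to_pearson(-1.0) == pytest.approx(-1.0)
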