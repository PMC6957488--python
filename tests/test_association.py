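"""Spearman correlations: the statistic, time-domain tables, CAI tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from oxyflow import (
    DegenerateSignalError,
    EpochSpec,
    ParameterError,
    StudyDesign,
    SyntheticConfig,
    cai_correlations,
    generate_cohort,
    spearman,
    timecourse_correlations,
)
from oxyflow.records import PERFUSION_CHANNELS


class TestSpearman:
    def test_monotone_affine_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, 2 * x + 3).rho == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 4]
        assert spearman(x, y).rho == pytest.approx(
            oracles.spearman_bruteforce(x, y), abs=1e-12)

    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_midrank_oracle(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.integers(-5, 5, size=len(xs)).tolist()
        res = spearman(np.array(xs, float), np.array(ys, float))
        if math.isnan(res.rho):
            assert len(set(xs)) == 1 or len(set(ys)) == 1
        else:
            assert res.rho == pytest.approx(
                oracles.spearman_bruteforce(xs, ys), abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert spearman(x, y).rho == spearman(y, x).rho

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        from scipy.stats import rankdata
        assert spearman(rankdata(x), y).rho == pytest.approx(base, abs=1e-12)

    def test_constant_input_flagged(self):
        res = spearman(np.ones(5), np.arange(5.0))
        assert math.isnan(res.rho)
        assert "constant" in res.note

    def test_needs_three(self):
        with pytest.raises(ParameterError):
            spearman([1.0, 2.0], [1.0, 2.0])

    def test_exact_p_limited_to_small_n(self, rng):
        with pytest.raises(ParameterError):
            spearman(rng.standard_normal(11), rng.standard_normal(11),
                     p_method="exact")

    def test_t_and_exact_p_agree_on_decisions(self, rng):
        # accept/reject agreement at alpha=0.05 on >= 95% of random draws
        agree = 0
        trials = 60
        for _ in range(trials):
            n = int(rng.integers(5, 9))
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            p_t = spearman(x, y).p
            p_e = spearman(x, y, p_method="exact").p
            agree += (p_t < 0.05) == (p_e < 0.05)
        assert agree / trials >= 0.95


class TestTimecourseCorrelations:
    def test_oxy_against_itself_is_one(self, mini_cohort, mini_spec):
        df = timecourse_correlations(mini_cohort, mini_spec,
                                     epoch="stimulation",
                                     pairs=(("oxy_sat", "oxy_sat"),))
        assert (df["rho"] == 1.0).all()

    def test_configured_ordering_recovered(self):
        # ground truth: coupling 0.6 at 38 deg C, 0 at BC, -0.3 at 44 deg C
        coupling = {}
        for ch in PERFUSION_CHANNELS:
            coupling[("38", ch)] = 0.6
            coupling[("BC", ch)] = 0.0
            coupling[("44", ch)] = -0.3
        means = {"38": [], "BC": [], "44": []}
        for seed in range(5):
            config = SyntheticConfig(
                epoch_minutes=(1, 1, 1), seed=seed, coupling=coupling,
                baseline_coupling={ch: 0.0 for ch in PERFUSION_CHANNELS})
            design = StudyDesign(ts_subjects=4, bc_subjects=4, seed=seed)
            records = []
            from oxyflow.synthetic import generate_subject
            for sid in design.bc_ids:
                records.extend(generate_subject(sid, "BC", design, config))
            for sid in design.ts_ids:
                for cond in ("38", "44"):
                    records.extend(generate_subject(sid, cond, design, config))
            df = timecourse_correlations(records, config.epoch_spec,
                                         epoch="stimulation",
                                         pairs=(("V1", "oxy_sat"),))
            for cond in means:
                means[cond].append(df[df["condition"] == cond]["rho"].mean())
        assert np.mean(means["38"]) > np.mean(means["BC"]) > np.mean(means["44"])

    def test_missing_channel_skipped_with_warning(self, mini_cohort, mini_spec,
                                                  caplog):
        records = [r for r in mini_cohort if r.channel != "V2"]
        with caplog.at_level("WARNING", logger="oxyflow.association"):
            df = timecourse_correlations(records, mini_spec, epoch="baseline")
        assert not (df["pair"] == "V2~oxy_sat").any()
        assert (df["pair"] == "V1~oxy_sat").any()
        assert any("channel missing" in m for m in caplog.messages)

    def test_minute_mean_mode(self):
        from oxyflow.synthetic import generate_subject
        config = SyntheticConfig(epoch_minutes=(5, 5, 5), seed=7)
        design = StudyDesign(ts_subjects=1, bc_subjects=1, seed=7)
        records = generate_subject("BC01", "BC", design, config)
        df = timecourse_correlations(records, config.epoch_spec,
                                     epoch="baseline", use_minute_means=True)
        # 5-min epoch at 3 Hz: 900 raw samples but only 4 whole-minute means
        assert (df["n"] == 4).all()


class TestCaiCorrelations:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["subject_id", "condition",
                                           "channel", "cai"])

    def test_comonotone_jitter_gives_one(self):
        rows = []
        for i, jitter in enumerate([0.1, 0.5, 0.9, 0.2, 0.7]):
            rows.append((f"S{i}", "BC", "oxy_sat", 10 + jitter))
            rows.append((f"S{i}", "BC", "V1", 20 + jitter))
            rows.append((f"S{i}", "BC", "V2", 20 - jitter))
            rows.append((f"S{i}", "BC", "V3", 20 + jitter))
        res = cai_correlations(self._table(rows), "BC")
        by_pair = {r.pair: r.rho for r in res}
        assert by_pair[("V1", "oxy_sat")] == pytest.approx(1.0)
        assert by_pair[("V2", "oxy_sat")] == pytest.approx(-1.0)

    def test_missing_cais_dropped_pairwise(self):
        rows = []
        for i in range(6):
            rows.append((f"S{i}", "38", "oxy_sat", float(i)))
            rows.append((f"S{i}", "38", "V1", float(i) if i < 4 else np.nan))
            rows.append((f"S{i}", "38", "V2", float(i)))
            rows.append((f"S{i}", "38", "V3", float(i)))
        res = cai_correlations(self._table(rows), "38")
        by_pair = {r.pair: r for r in res}
        assert by_pair[("V1", "oxy_sat")].n == 4
        assert by_pair[("V2", "oxy_sat")].n == 6

    def test_too_few_complete_pairs(self):
        rows = [("S0", "40", "oxy_sat", 1.0), ("S0", "40", "V1", 1.0),
                ("S1", "40", "oxy_sat", 2.0), ("S1", "40", "V1", 2.0)]
        rows += [(f"S{i}", "40", ch, 1.0) for i in range(2) for ch in ("V2", "V3")]
        with pytest.raises(DegenerateSignalError):
            cai_correlations(self._table(rows), "40")

    def test_shared_complexity_recovers_positive_rho(self):
        # per-subject white fraction drives both channels' complexity
        from oxyflow.entropy import EntropyParams
        from oxyflow.pipeline import compute_cai_table
        config = SyntheticConfig(epoch_minutes=(5, 5, 5), seed=21,
                                 white_fraction_jitter=0.5,
                                 complexity_linked=True,
                                 coupling={},
                                 baseline_coupling={})
        design = StudyDesign(ts_subjects=1, bc_subjects=12, seed=21)
        records = generate_cohort(design, config)
        records = [r for r in records if r.condition == "BC"]
        spec = config.epoch_spec
        tables = compute_cai_table(records, spec,
                                   {"after": spec.window("stimulation")},
                                   EntropyParams(max_scale=20),
                                   kinds=("MSE",))
        res = cai_correlations(tables["cai"], "BC", pairs=(("V1", "oxy_sat"),))
        assert res[0].rho > 0.5
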