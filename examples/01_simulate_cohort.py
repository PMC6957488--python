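"""Generate a small synthetic cohort and look at its structure.

The generator emulates EPOS-style recordings: per subject and condition a
30-min baseline, a 30-min probe-heating epoch and a 30-min post epoch at
3 Hz (shortened here to 2 min per epoch for speed), with five channels:
oxygen saturation, the speed-resolved perfusion components V1/V2/V3 and
the probe temperature set-point.
"""

from oxyflow import StudyDesign, SyntheticConfig, generate_cohort

config = SyntheticConfig(epoch_minutes=(2, 2, 2), seed=1)
design = StudyDesign(ts_subjects=3, bc_subjects=3, seed=1)
records = generate_cohort(design, config)

print(f"{len(records)} records "
      f"({3 + 3 * 4} subject-condition recordings x 5 channels)")
rec = records[0]
print(f"first record: {rec.subject_id} condition={rec.condition} "
      f"channel={rec.channel} n={rec.n_samples} at {rec.sampling_rate_hz} Hz")
print("stimulation orders per TS subject (randomized per subject):")
for sid, order in design.stimulation_order.items():
    print(f"  {sid}: {' -> '.join(order)} degC")
# Each TS subject is recorded once per temperature; BC subjects once,
# unheated. Sample counts per epoch are exact: minutes x 60 x rate.
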