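"""Per-subject Spearman correlation between speed-resolved perfusion and
oxygen saturation, before and during stimulation.

The generator is configured so that mild heating (38 degC) tightens the
perfusion-oxygenation association while strong heating (44 degC)
decouples it — the analysis recovers that ground truth from the
time-domain rank correlations.
"""

from oxyflow import StudyDesign, SyntheticConfig, timecourse_correlations
from oxyflow.records import PERFUSION_CHANNELS
from oxyflow.synthetic import generate_subject

coupling = {}
for ch in PERFUSION_CHANNELS:
    coupling[("38", ch)] = 0.6
    coupling[("BC", ch)] = 0.0
    coupling[("44", ch)] = -0.3
config = SyntheticConfig(epoch_minutes=(5, 5, 5), seed=3, coupling=coupling,
                         baseline_coupling={ch: 0.0 for ch in PERFUSION_CHANNELS})
design = StudyDesign(ts_subjects=6, bc_subjects=6, seed=3)

records = []
for sid in design.bc_ids:
    records.extend(generate_subject(sid, "BC", design, config))
for sid in design.ts_ids:
    for cond in ("38", "44"):
        records.extend(generate_subject(sid, cond, design, config))

for epoch in ("baseline", "stimulation"):
    df = timecourse_correlations(records, config.epoch_spec, epoch=epoch,
                                 pairs=(("V1", "oxy_sat"),))
    print(f"\n{epoch}: group-mean rho (V1 vs oxygen saturation)")
    print(df.groupby("condition")["rho"].mean().round(3).to_string())
# Baseline rho is near zero everywhere; during stimulation the configured
# ordering 38 > BC > 44 emerges.
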