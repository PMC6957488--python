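# oxyflow

Complexity and correlation analysis of skin oxygen-saturation and
speed-resolved blood-perfusion recordings under local thermal stimulation.

## The problem

Combined diffuse-reflectance / laser-Doppler probes (EPOS-style systems)
record, at 3 Hz, tissue oxygen saturation together with blood perfusion
resolved into speed components (V1 < 1 mm/s, V2 1–10 mm/s, V3 > 10 mm/s).
When the skin under the probe is heated (38–44 °C for 30 min, between a
30-min baseline and a 30-min recovery epoch), both the *level* and the
*structure* of these signals change. Two questions drive the analysis this
package implements:

1. How does heating change the **complexity** of the oxygen-saturation
   signal? Complexity is measured by multiscale entropy: the series
   x₁…x_N is coarse-grained into block means at scales τ = 1…20,

       y_j^(τ) = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,

   and at each scale the sample entropy SampEn(m=2, r=0.15·SD) =
   −ln(A/B) (MSE) or the fuzzy entropy FuzzyEn(m=2, r=0.15·SD, n=2)
   (MFE) is computed; the **complexity area index (CAI)** is the
   trapezoidal integral of the entropy-versus-scale curve. White noise is
   irregular at scale 1 but loses entropy under coarse-graining; 1/f-like
   signals keep it, so the CAI separates genuine multiscale complexity
   from mere randomness.

2. How does heating change the **association** between each perfusion
   component and oxygen saturation? Per subject, Spearman's ρ between the
   two series within an epoch; across subjects, Spearman's ρ between the
   channel CAIs. Condition effects are tested with a one-way F across the
   five groups (blank control and four temperatures; with 30 + 4×29 = 146
   recordings the omnibus df are (4, 141)) and seeded label-permutation
   posttests on all ten pairwise contrasts (two-sided, α = 0.05).

Because human recordings of this kind cannot be assumed available, the
package ships a **synthetic cohort generator** that emulates the protocol
with controllable ground truth: temperature-dependent response shape
(amplitude, time-to-peak, post-stimulation decay — none at the hottest
condition), signal complexity via a white/1-f noise mixture, and the
perfusion–oxygenation rank correlation via Gaussian shared-signal mixing
(a Spearman target ρ_s is mapped to the Pearson weight 2·sin(πρ_s/6)).
Every analysis stage can therefore be validated against known truth.

## Worked example

```python
from oxyflow import EntropyParams, generate_noise, mse_curve

params = EntropyParams(m=2, r=0.15, max_scale=20)
white = generate_noise(16_200, white_fraction=1.0, sd=1.0, seed=7)
pink  = generate_noise(16_200, white_fraction=0.0, sd=1.0, seed=8)
print(mse_curve(white, params).cai, mse_curve(pink, params).cai)
```

prints `27.15  32.55`: at matched SD the 1/f signal has the larger
entropy area — its scale-1 entropy is lower (1.80 vs 2.47) but it holds
near 1.69 out to scale 20 while white noise falls to 1.03. Running
`examples/03_timecourse_correlations.py` (couplings 0.6 at 38 °C, 0 in
the control, −0.3 at 44 °C) prints group-mean stimulation-epoch ρ of
0.603 / 0.021 / −0.297 — the configured ordering recovered — and
`examples/04_group_comparison.py` prints the full-design omnibus
`F(4,141) = 111.72` with all ten pairwise permutation posttests.

The `examples/` directory has one short script per capability:
simulation, entropy curves, time-domain correlations, group comparisons,
and the end-to-end pipeline. The same functionality is scriptable through
the thin `oxyflow` CLI (`simulate`, `timecourse`, `entropy`, `correlate`,
`compare`, `all`), which writes tidy TSVs stamped with a config hash so
identical runs are byte-identical.

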