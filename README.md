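# asckit

Dual-pathway evaluation of the aortic-stenosis (AS) continuum on synthetic
echocardiography phantoms.

Aortic stenosis progresses along a continuum — normal → valve sclerosis →
mild → moderate → severe — but its clinical grading relies on a chain of
manual measurements: the peak transvalvular jet velocity (V<sub>max</sub>)
from continuous-wave Doppler, the mean pressure gradient (mPG =
ejection-window average of the simplified-Bernoulli 4v²), the velocity–time
integrals (VTI) of the valve jet and of the left-ventricular outflow tract
(LVOT), the LVOT diameter D from the parasternal long-axis (PLAX) view, and
the continuity-equation valve area

    AVA = π (D/2)² · VTI_LVOT / VTI_AV .

`asckit` re-implements, at desk scale and fully on synthetic data, a
two-pathway automation of this workflow:

1. **Continuum pathway** — a small factorized (2+1)D convolutional video
   network scores PLAX / PSAX clips on a 0–100 continuum index (DLi-ASc).
   Stages map to ordered targets y ∈ {0, 0.25, 0.5, 0.75, 1} trained by
   negative Bernoulli likelihood, plus three auxiliary regression heads
   (V<sub>max</sub>, mPG, AVA) under
   `L = L_Bernoulli + λ·(MSE_Vmax + MSE_mPG + MSE_AVA)`.
   Patient scores average per view type, then across view types; severity
   cutoffs are midpoints between consecutive per-stage mean scores
   (reference cutoffs 24.6 / 45.4 / 53.7 / 69.7 ship as defaults).
2. **Conventional pathway** — spectral-Doppler envelope segmentation →
   velocity trace → per-cycle V<sub>max</sub>/mPG/VTI; PLAX anatomy
   segmentation → LVOT diameter → continuity-equation AVA; guideline
   staging with discordance and low-flow-low-gradient (LFLG) detection; a
   predictive-entropy gate halts unreliable automatic measurements (the
   continuum score is produced regardless).

Everything is trainable and testable without clinical data: the
`asckit.phantoms` generator renders seeded echo-like clips whose leaflet
opening shrinks (and brightness rises when calcified) with severity, and
Doppler spectrograms with a half-sine ejection profile whose V
<sub>max</sub>, mPG and VTI have closed forms — the analytic oracle for
every measurement stage. The neural components run on a small in-repo
numpy layer library with hand-written backprop (`asckit._nn`); no GPU or
deep-learning framework is needed.

Who is this for: researchers prototyping AS-continuum scoring or Doppler
quantification methods who need a fully controlled, ground-truthed test
bed, and readers who want a runnable, end-to-end account of the dual
pathway at desk scale.

## Worked example

```python
from asckit import ASMeasurements, stage_from_measurements, compute_ava_continuity
from asckit.phantoms import sample_cohort, analytic_truth, render_doppler
from asckit.doppler import measure_spectrum

# a severe-AS phantom, noiseless, fully seeded
spec = sample_cohort(1, class_mix=(0, 0, 0, 0, 1), seed=7, noise_level=0.0)[0]
truth = analytic_truth(spec)
spectrum, _ = render_doppler(spec, view="av_cw")
m = measure_spectrum(spectrum)
print(f"true   Vmax {truth.vmax:.2f} m/s   mPG {truth.mpg:.1f} mmHg   VTI {truth.av_vti:.1f} cm")
print(f"auto   Vmax {m.vmax:.2f} m/s   mPG {m.mpg:.1f} mmHg   VTI {m.av_vti:.1f} cm")

print(f"AVA(2.0 cm, 20 cm, 80 cm) = {compute_ava_continuity(2.0, 20.0, 80.0):.4f} cm^2")
r = stage_from_measurements(ASMeasurements(vmax=4.5, mpg=50, ava=0.8, calcified=True))
print(f"stage: {r.stage.name.lower()}  concordant: {r.concordant}")
r = stage_from_measurements(ASMeasurements(vmax=3.5, mpg=30, ava=0.9))
print(f"stage: {r.stage}  flags: {sorted(f.value for f in r.flags)}")
```

prints

```
true   Vmax 5.08 m/s   mPG 51.6 mmHg   VTI 88.5 cm
auto   Vmax 5.08 m/s   mPG 51.2 mmHg   VTI 88.5 cm
AVA(2.0 cm, 20 cm, 80 cm) = 0.7854 cm^2
stage: severe  concordant: True
stage: None  flags: ['lflg_severe_pattern']
```

The automated Doppler chain recovers the generator's analytic truth to
within a fraction of a percent; the continuity equation reproduces the
textbook value; fully concordant severe measurements stage as severe,
while a small valve area without severe-range velocity or gradient is
*not* forced into a stage — it is flagged as the LFLG-severe pattern for
review.

A full cohort run from the shell:

```bash
asckit phantom --n 50 --seed 7 --out cohort/        # render study bundles
asckit train   --cohort cohort/ --out model/        # continuum scorer
asckit run     --cohort cohort/ --model model/ --out reports.csv
asckit eval    --cohort cohort/ --model model/ --out metrics.json
```

## Layout

| module | contents |
|---|---|
| `asckit.phantoms` | seeded phantom generator + analytic ground truth |
| `asckit.staging` | severity table, discordance/LFLG logic, continuity equation |
| `asckit.doppler` | envelope → trace → ejection windows → Vmax/mPG/VTI |
| `asckit.plax` | PLAX anatomy measurement (LVOT diameter, calcification) |
| `asckit.segmenters` | learned envelope / PLAX segmenters (sklearn-style) |
| `asckit.continuum` | ordinal targets, losses, `ContinuumScorer`, cutoffs, saliency, embedding |
| `asckit.gating` | predictive entropy, MC-dropout decomposition, the gate |
| `asckit.pipeline` / `asckit.io` / `asckit.cli` | per-patient orchestration, bundles, CLI |

See `docs/methods.md` for the model assumptions, generator design and
numerical choices.
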