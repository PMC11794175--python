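# Methods

This note documents the models, the synthetic-data design and the numerical
choices behind `asckit`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The staging engine

Severity grading follows the standard table: Vmax bands < 2 / 2–2.9 / 3–3.9
/ ≥ 4 m/s; mPG bands < 20 / 20–39 / ≥ 40 mmHg; AVA bands > 1.5 / 1–1.5 /
≤ 1 cm²; a sub-2 m/s valve is *normal* or *sclerotic* depending on
calcification. Printed band gaps are closed as half-open intervals
([2, 3), [3, 4), [20, 40)) so every value falls in exactly one band; the
severe bounds are inclusive exactly as printed (≥ 4 m/s, ≥ 40 mmHg,
AVA ≤ 1 cm²). How clinicians resolve a value like 2.95 m/s is not
standardised; the half-open convention is this package's choice.

A low mPG (< 20 mmHg) or a large AVA (> 1.5 cm²) cannot distinguish a
normal valve from mild stenosis — those row entries only appear in the
mild definition as a *conjunction*. The engine therefore maps each
available parameter to the **set of stages it is compatible with**
(e.g. mPG < 20 ↦ {normal, sclerosis, mild}) and intersects:

* singleton → that stage, concordant;
* the {normal, sclerosis} pair → split by the calcification flag
  (normal-band with an `insufficient_data` flag when unknown);
* {normal, sclerosis, mild} with both mPG < 20 and AVA > 1.5 → mild (the
  printed mild row); with only one low parameter → mild-band with
  `insufficient_data` (a normal valve cannot be excluded);
* empty → **no stage is forced**: the result is indeterminate with
  discordance flags (`mild_to_moderate`, `moderate_to_severe` for
  Vmax-vs-mPG band splits, `lflg_severe_pattern` for AVA < 1 cm² without
  severe-range velocity or gradient). Unnamed disagreement patterns (e.g.
  Vmax-mild against AVA-moderate) are indeterminate without a named flag.

Refusing to force a stage mirrors how discordant readings are excluded
from consistent ground-truth labelling, and it is what makes the LFLG
pattern visible downstream rather than silently mis-staged.

## The phantom generator

The generator's job is to make every downstream stage trainable and
testable with known answers, not to simulate acoustics. Each patient spec
draws: stage, Vmax (uniform in a stage band), heart rate (60–85 bpm),
ejection duration T_ej (0.26–0.32 s, always shorter than the cycle), LVOT
diameter (1.9–2.3 cm), and a target AVA in the stage band; the LVOT VTI is
then *solved* from the continuity equation so the generated record is
internally concordant by construction.

Generative identities (the analytic oracle):

* ejection profile v(t) = Vmax·sin(πt/T_ej) — chosen because it gives
  closed forms, not as a physiological claim;
* VTI = (2/π)·Vmax·T_ej·100 cm (integral of the half-sine);
* mPG = 2·Vmax² mmHg (ejection-window mean of 4v² over a half-sine);
* AVA = π(D/2)²·VTI_LVOT/VTI_AV.

Because mPG is tied to Vmax, a moderate-band Vmax below √10 ≈ 3.16 m/s
would imply a mild-band mPG (and a severe-band Vmax below √20 ≈ 4.47 m/s a
moderate-band mPG). Cohort sampling therefore draws moderate Vmax from
[3.20, 3.85] and severe from [4.55, 5.40] so every spec stages
concordantly; AVA draws also keep a margin from the 1.0/1.5 cm² boundaries
so a ±1–2 px diameter measurement cannot flip a band. These margins are
part of the study conditions and are asserted by a cross-module test
(every sampled spec passes the staging engine with its true stage).

**Videos.** PLAX frames draw a simplified anatomy (LV cavity, septum,
posterior wall, LA, RV, aortic root, mitral leaflet, two aortic leaflets)
on a 6.4 cm field of view; PSAX-at-AV frames draw the root ring with three
leaflets. At the default 128 px resolution the pixel spacing is 0.05
cm/px (scaled for other resolutions). Severity is encoded in the two
channels a clinician actually reads in 2D: the peak systolic leaflet
opening fraction falls linearly with stage ordinal (1.00, 0.82, 0.64,
0.46, 0.28), and calcified leaflets render brighter (0.92 vs 0.55).
Clips cover exactly one cardiac cycle; the opening follows a half-sine
within the ejection window, so the mid-systolic frame is known. Speckle is
multiplicative-plus-additive Gaussian noise scaled by `noise_level`
(default 0.3 for cohorts; 0 is bit-reproducible rendering). What the
phantoms deliberately do **not** model: beam physics, realistic speckle
statistics, view foreshortening, arrhythmia, and pathologies other than
AS — so passing tests demonstrate method correctness on controlled
geometry, not clinical performance.

**Spectrograms.** Velocity rows at 0.02 m/s per row (baseline row 8, flow
rendered below the baseline), time at 1/256 s per column, three cycles per
strip. The envelope is filled to rint(v/Δv) rows, so a noiseless
spectrogram inverts to the truth trace within one row — the stated
resolution bound for the measurement chain.

## Doppler quantification

Envelope providers: (i) a deterministic oracle — intensity threshold at
the mid-range plus removal of connected components smaller than 20% of the
largest (each ejection cycle is its own component and survives); (ii) a
learned binary segmenter (below). The velocity trace takes, per column,
the furthest mask pixel from the baseline on the configured flow side.

Ejection windows are found as maximal runs with v ≥ 0.15·Vmax lasting
≥ 0.1 s, then expanded outward to the surrounding zero-velocity boundary
(including the bounding zero samples). The expansion matters: averaging
4v² over only the above-threshold run drops the low-velocity tails and
overestimates mPG by ~10% on a half-sine; over the full closed support the
trapezoidal mPG and VTI converge to the closed forms within a fraction of
a percent at 1 ms sampling.

Per window: Vmax = max v; mPG = trapezoidal time-average of 4v²; VTI =
trapezoidal ∫v dt in cm. Across cycles the default policy averages mPG and
VTI and takes the global maximum for Vmax ("max" aggregation is available;
the multi-cycle policy is a package convention).

## PLAX measurement

The LVOT diameter is measured on a label map: the annulus is the contact
line between LV and aorta classes; its direction is the principal axis of
the contact pixels; the diameter is the length of the lumen run (LV,
aorta, valve classes) along that line through the contact centroid, plus
one pixel for the half-pixel edges, times the pixel spacing. Over a clip
the median of the three most-open frames is reported (mid-systole, inner
edge to inner edge). The rule is purely geometric, hence rotation
invariant and identical for truth maps and learned maps. Measurement at
the annulus itself is the default; `offset_cm` shifts the plane into the
LVOT for conventions that measure slightly below the valve.

Calcification is read as the mean image intensity over valve-class pixels
against a fixed 0.75 threshold — possible because the phantoms encode
calcification as leaflet brightness; on real data this would be a
human reading or a separate classifier.

## Learned segmenters

Both providers share a small fully-convolutional encoder–decoder (two
3×3 stages, stride-2 bottleneck with dropout 0.15, nearest-neighbour
upsampling; ~7k parameters) trained with per-pixel softmax cross-entropy
and Adam (lr 3e-3) on phantom (image, truth-mask) pairs:

* **Envelope segmenter** — inputs: intensity + the signed velocity
  coordinate of each row relative to the baseline (so the rule transfers
  across spectrogram sizes); trained on random full-height column strips.
* **PLAX segmenter** — inputs: intensity + normalised x/y coordinates
  (standardised views make anatomy position-structured; the coordinate
  prior is intentional). Thin rare classes are upweighted in the loss
  (valve ×4, mitral ×2, background ×0.5) so leaflets are not drowned out
  by the chambers.

Monte-Carlo dropout passes (default 8) provide stochastic probability
maps for the uncertainty decomposition.

## The continuum scorer

Backbone: four factorized (2+1)D blocks — per-frame 3×3 spatial
convolution followed by a 3-tap temporal convolution, spatial strides
(2, 2, 2, 1) and temporal strides 2 — taking 16 frames at 64×64 to a
32-channel 8×8 map, then global average pooling, a 32-unit penultimate
dense layer, and four outputs: the continuum logit and three auxiliary
regressors (~22k parameters). Inputs are resampled to the configured clip
geometry and scaled to [−1, 1].

Training: Adam (lr 3e-3, batch 16), internal 15% validation split, early
stopping (patience 10) on the validation combined loss with best-weight
restore; everything derives from one seed, so trajectories are
reproducible and the λ = 0 and all-auxiliary-masked runs are bit-identical.
The Bernoulli loss is cross-entropy with soft targets, probabilities
clamped to [1e−7, 1−1e−7]; note its minimum over p sits at p = y with a
non-zero floor (e.g. 0.5623 at y = 0.75), which is why capacity checks use
binary-extreme targets. λ defaults to 1.0 with auxiliary targets
z-normalised by training-split statistics; unavailable targets are masked
out of their MSE term. DLi-ASc = 100 × sigmoid(logit).

Cutoffs are derived at the patient level as midpoints of consecutive
per-stage mean scores; classification at a cutoff is inclusive upward.
The shipped defaults (24.6 / 45.4 / 53.7 / 69.7) are the clinically derived
reference values; phantom-trained models can re-derive their own.

**Saliency** is the gradient-weighted activation magnitude at the last
convolutional stage, Σ_c |∂score/∂A_c · A_c|, upsampled and
max-normalised. The magnitude is used instead of the classic
channel-pooled, sign-rectified variant because influence on a *continuum*
output is informative in both directions — leaflet evidence that lowers
the score of a mild case is still where the model looked; on this
desk-scale network the channel-pooled variant failed to localise the
valve while the magnitude variant does so consistently.

**Embedding**: penultimate features projected to 2D with UMAP (15
neighbours, minimum distance 0.1, Euclidean metric, fixed seed).

## Uncertainty gating

Predictive entropy is the mean per-pixel entropy (nats) of a class
probability map. With MC-dropout passes it decomposes as predictive =
aleatoric + epistemic, where aleatoric is the mean per-pass entropy and
epistemic the mutual information (entropy of the mean map minus
aleatoric, clipped at 0). The gate halts the conventional pathway when
predictive entropy reaches the threshold (inclusive); halted measurements
propagate as unavailable, never as numbers; the continuum score is always
produced. The default threshold (0.15 nats) is a placeholder
calibrated per deployment via `calibrate_threshold` (95th percentile of
clean-reference entropies); gating is per study, on the mid-clip frame.

## Problem sizes and study conditions

The scaled-down experiments the suite runs: staging truth-table
equivalence on 10,000 random tuples; Doppler closed forms at 1 ms
sampling and scaling laws on 100 random traces; parameter recovery on a
150-patient (300-clip, both views) cohort at noise 0.3 with a
patient-level 80/20 split; segmentation Dice on 50 held-out phantoms;
end-to-end staging concordance on a 25-patient noiseless cohort with
oracle segmentation. These sizes were chosen as the smallest that
exercise every pathway stage with stable statistics on a single CPU.

## Known limitations

* The phantoms' severity encoding (leaflet excursion, brightness) is far
  cleaner than clinical video; recovery results bound method correctness,
  not clinical accuracy, and no clinical performance figure is claimed.
* The mPG ↔ Vmax coupling removes genuinely discordant physiology from
  generated cohorts; discordance handling is exercised through direct
  measurement records instead.
* The conventional pathway assumes the rendered view geometry (one PLAX
  clip, one CW + one PW spectrogram per study) and a readable
  calcification signal.
* Prognostic (survival) analysis and view classification are out of
  scope; view tags are consumed as metadata.
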