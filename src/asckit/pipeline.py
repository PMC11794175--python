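"""Per-patient dual-pathway orchestration and cohort evaluation.

The two pathways never exchange information before the report stage: the
continuum score is computed from PLAX/PSAX videos whenever they exist
(regardless of image quality), while the conventional pathway runs the
segmentation -> measurement chain and is subject to the uncertainty gate —
halted measurements propagate as unavailable, never as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import doppler as dop
from . import plax as plx
from .continuum import (DEFAULT_CUTOFFS, ContinuumScorer, aggregate_patient,
                        classify_by_cutoffs, score_video)
from .datatypes import (ASMeasurements, ASStage, CutoffSet, GateConfig,
                        PatientScore, Stage, UncertaintyReport)
from .gating import uncertainty_report
from .io import StudyBundle
from .phantoms import PhantomSpec, render_doppler, render_views
from .segmenters import EnvelopeSegmenter, PlaxSegmenter
from .staging import compute_ava_continuity, stage_from_measurements

__all__ = ["PatientReport", "make_bundle", "run_patient", "evaluate_cohort"]


@dataclass
class PatientReport:
    """Outcome of one dual-pathway run."""

    patient_id: str
    dli_asc: Optional[PatientScore]
    auto_measurements: ASMeasurements
    auto_stage: ASStage
    gate: Optional[UncertaintyReport]
    predicted_stage_by_cutoffs: Optional[Stage]


def make_bundle(spec: PhantomSpec, resolution: int = 128, n_frames: int = 16,
                include_truth: bool = True) -> StudyBundle:
    """Render a complete study bundle (videos + spectra + truth) from a spec."""
    plax_video, psax_video, truth = render_views(spec, resolution, n_frames)
    av_cw, _ = render_doppler(spec, view="av_cw")
    lvot_pw, _ = render_doppler(spec, view="lvot_pw")
    return StudyBundle(
        patient_id=spec.patient_id,
        videos=[plax_video, psax_video],
        spectra=[av_cw, lvot_pw],
        truth_measurements=truth.measurements if include_truth else None,
        truth_stage=spec.true_stage if include_truth else None,
        truth_label_maps=truth.label_map_truth if include_truth else None,
    )


def _conventional_pathway(bundle: StudyBundle,
                          plax_segmenter: Optional[PlaxSegmenter],
                          envelope_segmenter: Optional[EnvelopeSegmenter],
                          gate_config: GateConfig,
                          use_truth_maps: bool,
                          policy: str):
    """Measure what the available views allow; returns (measurements, gate)."""
    m = ASMeasurements()
    gate: Optional[UncertaintyReport] = None

    # ---- spectral Doppler -------------------------------------------------
    for spectrum in bundle.spectra:
        mask = (envelope_segmenter.predict_mask(spectrum)
                if envelope_segmenter is not None else None)
        got = dop.measure_spectrum(spectrum, mask=mask, policy=policy)
        for k in ("vmax", "mpg", "av_vti", "lvot_vti"):
            if getattr(got, k) is not None:
                m = m.replace(**{k: getattr(got, k)})

    # ---- PLAX anatomy -----------------------------------------------------
    plax_videos = [v for v in bundle.videos if v.view == "plax"]
    if plax_videos:
        video = plax_videos[0]
        maps = None
        if use_truth_maps and bundle.truth_label_maps is not None:
            from .datatypes import PlaxLabelMap

            maps = [PlaxLabelMap.from_labels(lab, video.pixel_spacing)
                    for lab in bundle.truth_label_maps]
            gate = UncertaintyReport(predictive_entropy=0.0, aleatoric=0.0,
                                     epistemic=0.0, gate="proceed")
        elif plax_segmenter is not None:
            mid = video.n_frames // 2
            passes = plax_segmenter.mc_probs(video.frames[mid],
                                             n_passes=gate_config.mc_samples)
            gate = uncertainty_report(passes, gate_config)
            if gate.gate == "proceed":
                maps = plx.segment_plax(video, plax_segmenter)
        if maps is not None:
            try:
                meas = plx.measure_lvot_diameter(maps)
                m = m.replace(lvot_diameter=meas.value)
                calc = plx.detect_calcification(video, maps)
                if calc is not None:
                    m = m.replace(calcified=calc)
            except ValueError:
                pass  # unmeasurable study: fields stay unavailable

    if m.lvot_diameter is not None and m.lvot_vti is not None and m.av_vti is not None:
        m = m.replace(ava=compute_ava_continuity(m.lvot_diameter, m.lvot_vti,
                                                 m.av_vti))
    return m, gate


def run_patient(bundle: StudyBundle,
                scorer: Optional[ContinuumScorer] = None,
                cutoffs: CutoffSet = DEFAULT_CUTOFFS,
                gate_config: Optional[GateConfig] = None,
                plax_segmenter: Optional[PlaxSegmenter] = None,
                envelope_segmenter: Optional[EnvelopeSegmenter] = None,
                use_truth_maps: bool = False,
                policy: str = "mean") -> PatientReport:
    """Run the dual pathway on one study bundle.

    The continuum pathway is always attempted when PLAX/PSAX videos exist
    and a trained scorer is supplied.  The conventional pathway consumes
    spectra and PLAX segmentations; ``use_truth_maps`` selects the oracle
    label-map provider, otherwise a trained ``plax_segmenter`` (gated by
    predictive entropy) is required for anatomy measurements.  When no
    envelope segmenter is given the deterministic threshold provider is
    used for Doppler.
    """
    gate_config = gate_config or GateConfig()

    dli: Optional[PatientScore] = None
    if scorer is not None:
        scorable = [v for v in bundle.videos if v.view in ("plax", "psax")]
        if scorable:
            dli = aggregate_patient(
                [(v.view, score_video(scorer, v)) for v in scorable])

    measurements, gate = _conventional_pathway(
        bundle, plax_segmenter, envelope_segmenter, gate_config,
        use_truth_maps, policy)

    auto_stage = stage_from_measurements(measurements)
    predicted = classify_by_cutoffs(dli.dli_asc, cutoffs) if dli is not None else None
    return PatientReport(patient_id=bundle.patient_id, dli_asc=dli,
                         auto_measurements=measurements, auto_stage=auto_stage,
                         gate=gate, predicted_stage_by_cutoffs=predicted)


# --------------------------------------------------------------------------
# cohort evaluation
# --------------------------------------------------------------------------

_TIERS = {
    "any": Stage.MILD,         # mild or greater
    "significant": Stage.MODERATE,  # moderate or greater
    "severe": Stage.SEVERE,
}


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    div = lambda a, b: a / b if b else float("nan")
    return {
        "sensitivity": div(tp, tp + fn), "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp), "npv": div(tn, tn + fn),
        "f1": div(2 * tp, 2 * tp + fp + fn),
    }


def evaluate_cohort(reports: Sequence[PatientReport],
                    truth: pd.DataFrame) -> dict:
    """Cohort metrics against a ground-truth table.

    ``truth`` needs a ``patient_id`` and ``stage`` column (stage names) and
    may carry ``vmax`` / ``mpg`` / ``ava`` / ``lvot_diameter`` columns for
    measurement agreement.  Returns AUCs for the any / significant / severe
    tiers of the continuum score, the staging confusion matrix and
    accuracy of the conventional pathway, Spearman r and MAE per measured
    parameter, and classification metrics of the cutoff-based stages.
    """
    from scipy.stats import spearmanr
    from sklearn.metrics import roc_auc_score

    truth = truth.set_index("patient_id")
    stages = []
    for r in reports:
        name = truth.loc[r.patient_id, "stage"]
        stages.append(Stage[str(name).upper()])
    ordinals = np.array([s.ordinal for s in stages])

    out: dict = {"n": len(reports)}

    scores = np.array([r.dli_asc.dli_asc if r.dli_asc is not None else np.nan
                       for r in reports])
    have_scores = ~np.isnan(scores)
    out["auc"] = {}
    for tier, floor in _TIERS.items():
        y = ordinals[have_scores] >= floor.ordinal
        if y.any() and not y.all():
            out["auc"][tier] = float(roc_auc_score(y, scores[have_scores]))
        else:
            out["auc"][tier] = None

    # staging concordance of the conventional pathway
    pred = [r.auto_stage.stage if r.auto_stage.concordant else None
            for r in reports]
    valid = [i for i, p in enumerate(pred) if p is not None]
    conf = np.zeros((5, 5), dtype=int)
    hits = 0
    for i in valid:
        conf[stages[i].ordinal, pred[i].ordinal] += 1
        hits += int(pred[i] == stages[i])
    out["staging"] = {
        "confusion": conf,
        "accuracy": hits / len(reports) if reports else float("nan"),
        "n_concordant": len(valid),
    }

    # measurement agreement
    out["measurements"] = {}
    for param in ("vmax", "mpg", "ava", "lvot_diameter"):
        if param not in truth.columns:
            continue
        pairs = [(getattr(r.auto_measurements, param),
                  float(truth.loc[r.patient_id, param]))
                 for r in reports if getattr(r.auto_measurements, param) is not None]
        if len(pairs) >= 3:
            a, t = map(np.asarray, zip(*pairs))
            out["measurements"][param] = {
                "spearman_r": float(spearmanr(a, t).statistic),
                "mae": float(np.mean(np.abs(a - t))),
                "n": len(pairs),
            }

    # cutoff-based classification metrics per tier
    cut_pred = np.array([r.predicted_stage_by_cutoffs.ordinal
                         if r.predicted_stage_by_cutoffs is not None else -1
                         for r in reports])
    out["cutoff_classification"] = {}
    for tier, floor in _TIERS.items():
        sel = cut_pred >= 0
        if sel.any():
            out["cutoff_classification"][tier] = _binary_metrics(
                ordinals[sel] >= floor.ordinal, cut_pred[sel] >= floor.ordinal)
    return out
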