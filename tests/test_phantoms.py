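"""Phantom generator: cohort sampling, rendering, analytic ground truth."""

import dataclasses
import math

import numpy as np
import pytest

from asckit.datatypes import ASMeasurements, Stage
from asckit.phantoms import (DopplerCalibration, PhantomSpec, analytic_truth,
                             envelope_truth_mask, leaflet_opening_gap,
                             render_doppler, render_views, sample_cohort)
from asckit.staging import stage_from_measurements


def _spec(stage=Stage.SEVERE, vmax=4.8, noise=0.0, seed=5, d=2.0):
    return PhantomSpec(patient_id="T", true_stage=stage, true_vmax=vmax,
                       ejection_duration=0.3, heart_rate=70.0,
                       true_lvot_diameter=d, true_lvot_vti=20.0,
                       calcified=stage >= Stage.SCLEROSIS,
                       noise_level=noise, seed=seed)


# ------------------------------------------------------------------ cohort

def test_cohort_counts_follow_mix():
    specs = sample_cohort(100, (0.2, 0.2, 0.2, 0.2, 0.2), seed=7)
    counts = {st: sum(s.true_stage == st for s in specs) for st in Stage}
    assert all(c == 20 for c in counts.values())


def test_cohort_specs_stage_concordant():
    """Cross-module oracle: every sampled spec stages as its true stage."""
    for s in sample_cohort(100, seed=7):
        result = stage_from_measurements(analytic_truth(s))
        assert result.concordant and result.stage == s.true_stage, s


def test_single_stage_mix():
    specs = sample_cohort(5, (1, 0, 0, 0, 0), seed=1)
    assert len(specs) == 5
    assert all(s.true_stage == Stage.NORMAL and s.true_vmax < 2 for s in specs)


def test_cohort_seeded_determinism():
    a = sample_cohort(20, seed=3)
    b = sample_cohort(20, seed=3)
    assert a == b
    assert a != sample_cohort(20, seed=4)


def test_bad_mix_rejected():
    with pytest.raises(ValueError):
        sample_cohort(10, (0.5, 0.5, 0.5, 0, 0))
    with pytest.raises(ValueError):
        sample_cohort(0)


def test_spec_validation():
    with pytest.raises(ValueError):  # vmax outside the stage band
        _spec(stage=Stage.MILD, vmax=3.5)
    with pytest.raises(ValueError):  # normal valves are not calcified
        PhantomSpec("x", Stage.NORMAL, 1.5, 0.3, 70, 2.0, 20.0, calcified=True)
    with pytest.raises(ValueError):  # ejection longer than the cycle
        PhantomSpec("x", Stage.NORMAL, 1.5, 1.0, 70, 2.0, 20.0, calcified=False)


# ----------------------------------------------------------- analytic truth

def test_analytic_truth_closed_forms():
    s = _spec(vmax=4.0)
    t = analytic_truth(s)
    assert t.mpg == pytest.approx(32.0)
    assert t.av_vti == pytest.approx((2 / math.pi) * 4.0 * 0.3 * 100)
    # continuity identity with the stated numbers
    m = ASMeasurements(lvot_diameter=2.0, lvot_vti=20.0, av_vti=80.0)
    from asckit.staging import compute_ava_continuity
    assert compute_ava_continuity(m.lvot_diameter, m.lvot_vti, m.av_vti) == \
        pytest.approx(0.7854, abs=5e-5)


# -------------------------------------------------------------- video views

def test_rendering_is_deterministic():
    a1, s1, _ = render_views(_spec(noise=0.3), 64, 16)
    a2, s2, _ = render_views(_spec(noise=0.3), 64, 16)
    assert np.array_equal(a1.frames, a2.frames)
    assert np.array_equal(s1.frames, s2.frames)


def test_leaflet_excursion_decreases_with_stage():
    gaps = []
    for stage in Stage:
        vmax = {0: 1.5, 1: 1.5, 2: 2.5, 3: 3.5, 4: 4.8}[stage.ordinal]
        spec = _spec(stage=stage, vmax=vmax)
        _, _, truth = render_views(spec, 128, 16)
        gaps.append(max(leaflet_opening_gap(lab, 0.05)
                        for lab in truth.label_map_truth))
    assert all(a > b for a, b in zip(gaps, gaps[1:]))


def test_calcified_leaflets_are_brighter():
    scl = _spec(stage=Stage.SCLEROSIS, vmax=1.5)
    norm = dataclasses.replace(scl, true_stage=Stage.NORMAL, calcified=False)
    v_s, _, t_s = render_views(scl, 128, 16)
    v_n, _, t_n = render_views(norm, 128, 16)
    r0, c0, r1, c1 = t_s.leaflet_box["plax"]
    assert v_s.frames[:, r0:r1, c0:c1].mean() > v_n.frames[:, r0:r1, c0:c1].mean()


def test_leaflet_box_inside_frame_and_peak_frame():
    _, _, truth = render_views(_spec(), 64, 16)
    for view in ("plax", "psax"):
        r0, c0, r1, c1 = truth.leaflet_box[view]
        assert 0 <= r0 < r1 <= 64 and 0 <= c0 < c1 <= 64
    assert truth.opening.argmax() == truth.peak_frame


def test_render_views_preconditions():
    with pytest.raises(ValueError):
        render_views(_spec(), resolution=16)
    with pytest.raises(ValueError):
        render_views(_spec(), resolution=64, n_frames=4)


# ----------------------------------------------------------------- doppler

def test_doppler_truth_closed_forms():
    spec = _spec(vmax=4.0)
    spectrum, trace = render_doppler(spec, view="av_cw")
    # truth trace integrates to the closed-form VTI and mean 4v^2 to mPG
    sel = trace.velocities > 0
    assert trace.velocities.max() == pytest.approx(4.0, rel=0.01)
    vti = np.trapezoid(trace.velocities, trace.times) * 100 / 3  # 3 cycles
    assert vti == pytest.approx((2 / math.pi) * 4.0 * 0.3 * 100, rel=0.01)


def test_doppler_envelope_inverts_to_truth():
    """Noise 0: per-column envelope top maps back within one row."""
    spec = _spec(vmax=3.0, stage=Stage.MODERATE, noise=0.0)
    spectrum, trace = render_doppler(spec)
    img = spectrum.intensity
    filled = img >= 0.5
    depth = np.where(filled.any(axis=0),
                     filled[::-1].argmax(axis=0), 0)
    depth = np.where(filled.any(axis=0),
                     img.shape[0] - 1 - depth - spectrum.baseline_row, 0)
    v_rec = depth * spectrum.velocity_per_row
    assert np.max(np.abs(v_rec - trace.velocities)) <= spectrum.velocity_per_row


def test_doppler_validation_errors():
    with pytest.raises(ValueError):  # axis too short for the jet
        render_doppler(_spec(vmax=5.0), DopplerCalibration(n_rows=100))
    with pytest.raises(ValueError):
        render_doppler(_spec(), view="mitral")


def test_doppler_rendering_deterministic():
    s = _spec(noise=0.4)
    a, _ = render_doppler(s)
    b, _ = render_doppler(s)
    assert np.array_equal(a.intensity, b.intensity)


def test_envelope_truth_mask_matches_render():
    spec = _spec(noise=0.0)
    spectrum, trace = render_doppler(spec)
    mask = envelope_truth_mask(spectrum, trace)
    assert np.array_equal(mask, spectrum.intensity >= 0.5)
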