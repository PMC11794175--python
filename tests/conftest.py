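"""Shared fixtures: phantom cohorts and the trained desk-scale models.

The expensive artifacts (rendered cohort, trained scorer and segmenters)
are session-scoped so every test that needs a trained model reuses one
training run.  All randomness is seeded; the cohort conditions (sizes,
noise level, class mix) are the package defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from asckit.continuum import ContinuumScorer, ordinal_target
from asckit.phantoms import (analytic_truth, envelope_truth_mask, render_doppler,
                             render_views, sample_cohort)
from asckit.segmenters import EnvelopeSegmenter, PlaxSegmenter


class Cohort:
    """A rendered two-view cohort (one PLAX + one PSAX clip per patient).

    Videos of both views are pooled; the train/test split is by patient so
    no patient contributes clips to both sides.
    """

    def __init__(self, n_patients=150, seed=11, noise=0.3, resolution=64,
                 n_frames=16):
        self.specs = sample_cohort(n_patients, seed=seed, noise_level=noise)
        videos, targets, aux, boxes, views, patient = [], [], [], [], [], []
        for i, s in enumerate(self.specs):
            plax, psax, truth = render_views(s, resolution=resolution,
                                             n_frames=n_frames)
            t = truth.measurements
            for clip, view in ((plax, "plax"), (psax, "psax")):
                videos.append(clip.frames)
                targets.append(ordinal_target(s.true_stage))
                aux.append([t.vmax, t.mpg, t.ava])
                boxes.append(truth.leaflet_box[view])
                views.append(view)
                patient.append(i)
        self.videos = np.array(videos)
        self.y = np.array(targets)
        self.aux = np.array(aux)
        self.boxes = boxes
        self.views = views
        self.patient = np.array(patient)
        stage_of = np.array([s.true_stage.ordinal for s in self.specs])
        self.stages = stage_of[self.patient]
        rng = np.random.default_rng(0)
        perm = rng.permutation(n_patients)
        test_patients = set(perm[:n_patients // 5].tolist())
        idx = np.arange(len(videos))
        self.test_idx = idx[np.isin(self.patient, list(test_patients))]
        self.train_idx = idx[~np.isin(self.patient, list(test_patients))]


@pytest.fixture(scope="session")
def cohort300() -> Cohort:
    return Cohort(n_patients=150, seed=11, noise=0.3)


@pytest.fixture(scope="session")
def scorer300(cohort300) -> ContinuumScorer:
    """The parameter-recovery scorer trained on the 240-video train split."""
    tr = cohort300.train_idx
    scorer = ContinuumScorer(epochs=40, random_state=0)
    scorer.fit(list(cohort300.videos[tr]), cohort300.y[tr], aux=cohort300.aux[tr])
    return scorer


@pytest.fixture(scope="session")
def doppler_set():
    """(spectrum, truth mask, spec) triples at the default noise level."""
    specs = sample_cohort(90, seed=21, noise_level=0.3)
    out = []
    for s in specs:
        spectrum, trace = render_doppler(s, view="av_cw")
        out.append((spectrum, envelope_truth_mask(spectrum, trace), s))
    return out


@pytest.fixture(scope="session")
def envelope_segmenter(doppler_set) -> EnvelopeSegmenter:
    seg = EnvelopeSegmenter(n_iter=150, random_state=0)
    seg.fit([d[0] for d in doppler_set[:40]], [d[1] for d in doppler_set[:40]])
    return seg


@pytest.fixture(scope="session")
def plax_segmenter() -> PlaxSegmenter:
    specs = sample_cohort(40, seed=21, noise_level=0.3)
    frames, labels = [], []
    for s in specs:
        plax, _, truth = render_views(s, resolution=64, n_frames=16)
        for k in (2, 4, 8):
            frames.append(plax.frames[k])
            labels.append(truth.label_map_truth[k])
    return PlaxSegmenter(n_iter=300, random_state=0).fit(frames, labels)
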