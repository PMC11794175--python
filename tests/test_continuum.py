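"""Continuum pathway: losses, aggregation, cutoffs, training behaviour."""

import math

import numpy as np
import pytest

from asckit.continuum import (DEFAULT_CUTOFFS, ContinuumScorer, aggregate_patient,
                              classify_by_cutoffs, derive_cutoffs, embed_features,
                              loss_bernoulli, loss_combined, ordinal_target,
                              saliency_map, score_video)
from asckit.datatypes import CutoffSet, EchoVideo, Stage


# ------------------------------------------------------------ targets/losses

def test_ordinal_mapping_is_exact():
    expected = {Stage.NORMAL: 0.0, Stage.SCLEROSIS: 0.25, Stage.MILD: 0.5,
                Stage.MODERATE: 0.75, Stage.SEVERE: 1.0}
    for stage, y in expected.items():
        assert ordinal_target(stage) == y


@pytest.mark.parametrize("p, y, expected", [
    (0.5, 1.0, math.log(2)),
    (0.75, 0.75, -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
])
def test_bernoulli_loss_values(p, y, expected):
    assert loss_bernoulli(p, y) == pytest.approx(expected, abs=1e-6)


def test_bernoulli_loss_limit_and_validation():
    assert loss_bernoulli(1e-9, 0.0) < 1e-5  # clamped, -> 0
    with pytest.raises(ValueError):
        loss_bernoulli(0.5, 1.2)


def test_bernoulli_minimised_at_p_equals_y():
    grid = np.linspace(0.001, 0.999, 999)
    for y in (0.0, 0.25, 0.5, 0.75, 1.0):
        losses = [loss_bernoulli(p, y) for p in grid]
        p_star = grid[int(np.argmin(losses))]
        assert abs(p_star - y) <= 0.002 or y in (0.0, 1.0) and (
            p_star <= 0.002 or p_star >= 0.998)


def test_combined_loss_reductions():
    preds = np.array([[0.5, 0.0, 0.0]])
    targs = np.zeros((1, 3))
    mask = np.ones((1, 3), bool)
    base = loss_bernoulli(0.5, 0.5)
    assert loss_combined(0.5, 0.5, preds, targs, mask, 0.0) == base
    assert loss_combined(0.5, 0.5, preds, targs, np.zeros((1, 3), bool), 3.0) == base
    # residuals (0.5, 0, 0) at lambda=1 add 0.25
    assert loss_combined(0.5, 0.5, preds, targs, mask, 1.0) == \
        pytest.approx(base + 0.25, abs=1e-9)
    with pytest.raises(ValueError):
        loss_combined(0.5, 0.5, preds, targs, mask, -1.0)


# ------------------------------------------------------------- aggregation

def test_patient_aggregation_rule():
    ps = aggregate_patient([("plax", 60), ("plax", 70), ("psax", 50)])
    assert ps.per_view_mean == {"plax": 65.0, "psax": 50.0}
    assert ps.dli_asc == pytest.approx(57.5)


def test_single_view_used_directly():
    assert aggregate_patient([("psax", 40), ("psax", 60)]).dli_asc == 50.0
    assert aggregate_patient([("plax", 42)]).dli_asc == 42.0


def test_aggregation_order_invariant_and_bounded():
    scores = [("plax", 30), ("psax", 80), ("plax", 50), ("psax", 20)]
    a = aggregate_patient(scores).dli_asc
    b = aggregate_patient(scores[::-1]).dli_asc
    assert a == b
    vals = [s for _, s in scores]
    assert min(vals) <= a <= max(vals)
    with pytest.raises(ValueError):
        aggregate_patient([])


# ----------------------------------------------------------------- cutoffs

def test_derive_cutoffs_midpoints():
    scores = [5, 5, 20, 20, 50, 50, 60, 60, 80, 80]
    stages = [Stage.NORMAL] * 2 + [Stage.SCLEROSIS] * 2 + [Stage.MILD] * 2 + \
             [Stage.MODERATE] * 2 + [Stage.SEVERE] * 2
    cuts = derive_cutoffs(scores, stages)
    assert cuts.as_tuple() == (12.5, 35.0, 55.0, 70.0)


def test_derive_cutoffs_names_missing_stages():
    with pytest.raises(ValueError, match="severe"):
        derive_cutoffs([1, 2], [Stage.NORMAL, Stage.SCLEROSIS])


def test_reference_cutoffs_and_classification():
    assert DEFAULT_CUTOFFS.as_tuple() == (24.6, 45.4, 53.7, 69.7)
    assert classify_by_cutoffs(70.0) == Stage.SEVERE
    assert classify_by_cutoffs(10.0) == Stage.NORMAL
    assert classify_by_cutoffs(53.7) == Stage.MODERATE  # boundary inclusive
    assert classify_by_cutoffs(24.6) == Stage.SCLEROSIS
    with pytest.raises(ValueError):
        classify_by_cutoffs(101.0)
    with pytest.raises(ValueError):
        CutoffSet(30, 20, 50, 60)


# ---------------------------------------------------------------- training

def _tiny_videos(n, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 16, 32, 32)).astype(np.float32)
    return X


def test_single_class_dataset_rejected():
    X = _tiny_videos(6)
    with pytest.raises(ValueError):
        ContinuumScorer(epochs=1).fit(list(X), [0.5] * 6)


def test_training_is_deterministic():
    X = _tiny_videos(10)
    y = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    a = ContinuumScorer(epochs=3, random_state=5).fit(list(X), y)
    b = ContinuumScorer(epochs=3, random_state=5).fit(list(X), y)
    assert [h["val_loss"] for h in a.history_] == [h["val_loss"] for h in b.history_]


def test_lambda_zero_equals_all_masked():
    X = _tiny_videos(10)
    y = [0, 1] * 5
    aux = np.random.default_rng(2).random((10, 3))
    a = ContinuumScorer(epochs=3, lambda_weight=0.0, random_state=5).fit(
        list(X), y, aux=aux)
    b = ContinuumScorer(epochs=3, lambda_weight=1.0, random_state=5).fit(
        list(X), y, aux=aux, aux_mask=np.zeros((10, 3), bool))
    assert [h["train_loss"] for h in a.history_] == \
        [h["train_loss"] for h in b.history_]


def test_capacity_overfit_binary_targets(cohort300):
    """10 normal/severe clips are driven below Bernoulli loss 0.1."""
    idx = np.concatenate([np.flatnonzero(cohort300.stages == 0)[:5],
                          np.flatnonzero(cohort300.stages == 4)[:5]])
    sc = ContinuumScorer(epochs=200, lambda_weight=0.0, val_fraction=0.0,
                         patience=10_000, random_state=0)
    sc.fit(list(cohort300.videos[idx]), cohort300.y[idx])
    assert sc.history_[-1]["train_loss"] < 0.1


def test_scores_bounded_and_views_validated(scorer300, cohort300):
    scores = scorer300.predict(list(cohort300.videos[cohort300.test_idx[:10]]))
    assert np.all((scores >= 0) & (scores <= 100))
    video = EchoVideo(cohort300.videos[0], "plax", 20.0, 0.1)
    assert 0 <= score_video(scorer300, video) <= 100
    bad = EchoVideo(cohort300.videos[0], "apical", 20.0, 0.1)
    with pytest.raises(ValueError):
        score_video(scorer300, bad)


def test_checkpoint_roundtrip(tmp_path, scorer300, cohort300):
    scorer300.save(tmp_path / "model")
    loaded = ContinuumScorer.load(tmp_path / "model")
    X = list(cohort300.videos[cohort300.test_idx[:5]])
    np.testing.assert_allclose(loaded.predict(X), scorer300.predict(X), atol=1e-9)


def test_aux_heads_learn_with_lambda(cohort300):
    """Held-out auxiliary MSE is lower with lambda=1 than with lambda=0."""
    tr = cohort300.train_idx[:150]
    te = cohort300.test_idx
    kw = dict(epochs=15, random_state=0)
    l1 = ContinuumScorer(lambda_weight=1.0, **kw).fit(
        list(cohort300.videos[tr]), cohort300.y[tr], aux=cohort300.aux[tr])
    l0 = ContinuumScorer(lambda_weight=0.0, **kw).fit(
        list(cohort300.videos[tr]), cohort300.y[tr], aux=cohort300.aux[tr])

    def mse(model):
        pred = model.predict_aux(list(cohort300.videos[te]))
        z = (pred - cohort300.aux[te]) / model.aux_std_
        return float(np.mean(z ** 2))

    assert mse(l1) < mse(l0)


# ---------------------------------------------------------------- saliency

def test_saliency_contract(scorer300, cohort300):
    video = cohort300.videos[cohort300.test_idx[0]]
    cam = saliency_map(scorer300, video)
    assert cam.shape == video.shape
    assert cam.min() >= 0.0
    assert cam.max() == pytest.approx(1.0)


def test_saliency_constant_video_handled(scorer300):
    cam = saliency_map(scorer300, np.full((16, 64, 64), 0.4, dtype=np.float32))
    assert cam.shape == (16, 64, 64)
    assert cam.min() >= 0.0 and cam.max() <= 1.0


def test_saliency_localises_leaflets(scorer300, cohort300):
    """Mean saliency inside the leaflet box beats outside on >= 70%."""
    wins = total = 0
    for i in cohort300.test_idx[:30]:
        cam = saliency_map(scorer300, cohort300.videos[i])
        r0, c0, r1, c1 = cohort300.boxes[i]
        inside = cam[:, r0:r1, c0:c1].mean()
        outside_mask = np.ones(cam.shape, bool)
        outside_mask[:, r0:r1, c0:c1] = False
        wins += inside > cam[outside_mask].mean()
        total += 1
    assert wins / total >= 0.7


# --------------------------------------------------------------- embedding

def test_embedding_shape_determinism_and_gradient(scorer300, cohort300):
    idx = cohort300.test_idx[:40]
    X = list(cohort300.videos[idx])
    feats, emb = embed_features(scorer300, X, seed=0)
    assert feats.shape == (40, 32)
    assert emb.shape == (40, 2)
    _, emb2 = embed_features(scorer300, X, seed=0)
    np.testing.assert_allclose(emb, emb2, atol=1e-6)
    # the severity gradient shows along the leading axis of the embedding
    from scipy.stats import spearmanr
    from sklearn.decomposition import PCA

    p1 = PCA(n_components=1).fit_transform(emb)[:, 0]
    rho = abs(spearmanr(p1, cohort300.stages[idx]).statistic)
    assert rho >= 0.6


def test_embedding_needs_enough_videos(scorer300, cohort300):
    with pytest.raises(ValueError):
        embed_features(scorer300, list(cohort300.videos[:8]))
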