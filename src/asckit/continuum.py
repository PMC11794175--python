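"""The deep-learning AS-continuum pathway.

Severity is treated as a continuum: each stage maps onto an ordered target
y in {0, 0.25, 0.5, 0.75, 1} (normal .. severe) and a small video network
with factorized spatial/temporal convolution blocks predicts a single
probability p trained by negative Bernoulli likelihood

    L_Bernoulli = -[ y ln p + (1 - y) ln(1 - p) ]

plus three auxiliary regression heads predicting Vmax, mPG and AVA
(z-normalised, masked where unavailable) under

    L_combined = L_Bernoulli + lambda * (L_MSE_Vmax + L_MSE_mPG + L_MSE_AVA).

The continuum score (DLi-ASc) is 100 * p per video; patient scores average
per view type and then across the available view types.  Severity cutoffs
are midpoints between consecutive per-stage mean scores; the clinically
derived reference cutoffs (24.6 / 45.4 / 53.7 / 69.7) ship as defaults.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import (Adam, Dense, GlobalAvgPool, ReLU, Sequential, SpatialConv3d,
                  TemporalConv)
from .datatypes import CutoffSet, EchoVideo, PatientScore, Stage

__all__ = [
    "ORDINAL_TARGETS",
    "DEFAULT_CUTOFFS",
    "ordinal_target",
    "loss_bernoulli",
    "loss_combined",
    "ContinuumScorer",
    "train_continuum_model",
    "score_video",
    "aggregate_patient",
    "derive_cutoffs",
    "classify_by_cutoffs",
    "saliency_map",
    "embed_features",
]

ORDINAL_TARGETS = {
    Stage.NORMAL: 0.0,
    Stage.SCLEROSIS: 0.25,
    Stage.MILD: 0.5,
    Stage.MODERATE: 0.75,
    Stage.SEVERE: 1.0,
}

#: clinically derived reference cutoffs for DLi-ASc
DEFAULT_CUTOFFS = CutoffSet(sclerosis=24.6, mild=45.4, moderate=53.7, severe=69.7)

_P_CLIP = 1e-7


def ordinal_target(stage: Stage) -> float:
    """Ordered continuum target of a severity stage."""
    return ORDINAL_TARGETS[Stage(stage)]


def loss_bernoulli(p: Union[float, np.ndarray], y: Union[float, np.ndarray]) -> float:
    """Negative Bernoulli log-likelihood with soft targets (mean over items)."""
    p = np.clip(np.asarray(p, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must lie in [0, 1]")
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def loss_combined(p, y, aux_preds, aux_targets, aux_mask, lambda_weight: float) -> float:
    """Bernoulli loss plus lambda times the summed masked auxiliary MSEs.

    ``aux_preds`` / ``aux_targets`` are (n, 3) in normalised units;
    ``aux_mask`` marks available targets.  A task with no available target
    contributes zero.
    """
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")
    total = loss_bernoulli(p, y)
    if lambda_weight == 0:
        return total
    aux_preds = np.atleast_2d(np.asarray(aux_preds, dtype=float))
    aux_targets = np.atleast_2d(np.asarray(aux_targets, dtype=float))
    mask = np.atleast_2d(np.asarray(aux_mask, dtype=bool))
    for k in range(aux_preds.shape[1]):
        mk = mask[:, k]
        if mk.any():
            resid = aux_preds[mk, k] - aux_targets[mk, k]
            total += lambda_weight * float(np.mean(resid ** 2))
    return total


@dataclass
class ModelConfig:
    """Serializable training configuration of a fitted scorer."""

    lambda_weight: float = 1.0
    n_frames: int = 16
    resolution: int = 64
    epochs: int = 60
    lr: float = 3e-3
    batch_size: int = 16
    random_state: int = 0


def _build_video_net(rng) -> tuple[Sequential, int, int]:
    """Factorized (2+1)D video network.

    Returns (net, index of the last conv activation for Grad-CAM, index of
    the penultimate activation for feature embedding).
    """
    net = Sequential([
        SpatialConv3d(1, 8, stride=2, rng=rng), ReLU(),      # 64 -> 32
        TemporalConv(8, 8, stride=2, rng=rng), ReLU(),       # 16 -> 8
        SpatialConv3d(8, 16, stride=2, rng=rng), ReLU(),     # 32 -> 16
        TemporalConv(16, 16, stride=2, rng=rng), ReLU(),     # 8 -> 4
        SpatialConv3d(16, 24, stride=2, rng=rng), ReLU(),    # 16 -> 8
        TemporalConv(24, 24, stride=2, rng=rng), ReLU(),     # 4 -> 2
        SpatialConv3d(24, 32, stride=1, rng=rng), ReLU(),    # 8 -> 8
        TemporalConv(32, 32, stride=2, rng=rng), ReLU(),     # 2 -> 1
        GlobalAvgPool(),
        Dense(32, 32, rng=rng), ReLU(),
        Dense(32, 4, rng=rng),                               # [logit, 3 aux]
    ])
    return net, 15, 18


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class ContinuumScorer(BaseEstimator):
    """Desk-scale video scorer for the AS continuum (DLi-ASc 0-100).

    Parameters
    ----------
    lambda_weight : weight of the auxiliary regression losses.
    n_frames, resolution : input clip geometry; clips are resampled to it.
    epochs, lr, batch_size : Adam training schedule.
    val_fraction, patience : internal validation split and early stopping
        on the validation combined loss (best weights are restored).
    random_state : seeds initialisation, the split and batch shuffling.
    """

    def __init__(self, lambda_weight=1.0, n_frames=16, resolution=64,
                 epochs=60, lr=3e-3, batch_size=16, val_fraction=0.15,
                 patience=10, random_state=0):
        self.lambda_weight = lambda_weight
        self.n_frames = n_frames
        self.resolution = resolution
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------ io
    def _prepare_clip(self, video: Union[EchoVideo, np.ndarray]) -> np.ndarray:
        frames = video.frames if isinstance(video, EchoVideo) else np.asarray(video)
        t, h, w = frames.shape
        if t != self.n_frames:
            idx = np.linspace(0, t - 1, self.n_frames).round().astype(int)
            frames = frames[idx]
        if (h, w) != (self.resolution, self.resolution):
            zoom = (1, self.resolution / h, self.resolution / w)
            frames = ndimage.zoom(frames, zoom, order=1)
            frames = frames[:, :self.resolution, :self.resolution]
        return frames.astype(np.float64) * 2.0 - 1.0

    def _as_batch(self, videos) -> np.ndarray:
        return np.stack([self._prepare_clip(v) for v in videos])[:, None]

    @staticmethod
    def _targets(y) -> np.ndarray:
        arr = []
        for v in y:
            arr.append(ordinal_target(v) if isinstance(v, (Stage, int, np.integer))
                       else float(v))
        out = np.asarray(arr, dtype=float)
        if np.any((out < 0) | (out > 1)):
            raise ValueError("ordinal targets must lie in [0, 1]")
        return out

    # ----------------------------------------------------------------- fit
    def fit(self, X, y, aux=None, aux_mask=None):
        """Train on clips X with ordinal targets y and optional aux targets.

        X : sequence of EchoVideo or (T, H, W) arrays.
        y : Stage values or floats in [0, 1].
        aux : (n, 3) raw Vmax / mPG / AVA targets; aux_mask marks available
            entries.  Z-normalisation statistics are learned from the
            training split.
        """
        yt = self._targets(y)
        if np.unique(yt).size < 2:
            raise ValueError("training targets span a single class")
        xb = self._as_batch(X)
        n = len(xb)
        if aux is None:
            aux = np.zeros((n, 3))
            aux_mask = np.zeros((n, 3), dtype=bool)
        aux = np.asarray(aux, dtype=float)
        aux_mask = (np.ones((n, 3), dtype=bool) if aux_mask is None
                    else np.asarray(aux_mask, dtype=bool))
        aux = np.where(aux_mask, aux, 0.0)

        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(n)
        n_val = max(int(round(self.val_fraction * n)), 1) if n >= 8 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if n_val == 0:
            tr_idx = perm

        m = aux_mask[tr_idx]
        s = np.where(m.sum(axis=0) > 0, m.sum(axis=0), 1)
        self.aux_mean_ = (aux[tr_idx] * m).sum(axis=0) / s
        var = ((aux[tr_idx] - self.aux_mean_) ** 2 * m).sum(axis=0) / s
        self.aux_std_ = np.where(var > 1e-12, np.sqrt(var), 1.0)
        aux_n = (aux - self.aux_mean_) / self.aux_std_

        self.net_, self.cam_index_, self.penult_index_ = _build_video_net(rng)
        opt = Adam(self.net_, lr=self.lr)
        self.history_ = []
        best_val, best_state, wait = math.inf, None, 0

        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            tr_loss = 0.0
            for b0 in range(0, len(order), self.batch_size):
                bi = order[b0:b0 + self.batch_size]
                out = self.net_.forward(xb[bi], train=True, rng=rng)
                loss, dout = self._loss_and_grad(out, yt[bi], aux_n[bi], aux_mask[bi])
                self.net_.backward(dout)
                opt.step()
                tr_loss += loss * len(bi)
            tr_loss /= len(order)
            if n_val:
                val_out = self.net_.forward(xb[val_idx])
                val_loss, _ = self._loss_and_grad(val_out, yt[val_idx],
                                                  aux_n[val_idx], aux_mask[val_idx])
            else:
                val_loss = tr_loss
            self.history_.append({"epoch": epoch, "train_loss": tr_loss,
                                  "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val, wait = val_loss, 0
                best_state = self.net_.state_dict()
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            self.net_.load_state_dict(best_state)
        return self

    def _loss_and_grad(self, out, y, aux_n, aux_mask):
        n = out.shape[0]
        p = np.clip(_sigmoid(out[:, 0]), _P_CLIP, 1.0 - _P_CLIP)
        loss = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        dout = np.zeros_like(out)
        dout[:, 0] = (p - y) / n
        lam = self.lambda_weight
        if lam > 0:
            for k in range(3):
                mk = aux_mask[:, k]
                cnt = int(mk.sum())
                if cnt == 0:
                    continue
                resid = (out[:, 1 + k] - aux_n[:, k]) * mk
                loss += lam * float(np.sum(resid ** 2) / cnt)
                dout[:, 1 + k] = lam * 2.0 * resid / cnt
        return loss, dout

    # ------------------------------------------------------------- predict
    def _forward_batched(self, X, keep: Optional[int] = None, batch: int = 32):
        outs, acts = [], []
        for b0 in range(0, len(X), batch):
            xb = self._as_batch(X[b0:b0 + batch])
            if keep is None:
                outs.append(self.net_.forward(xb))
            else:
                o, a = self.net_.forward(xb, keep_activation=keep)
                outs.append(o)
                acts.append(a)
        out = np.concatenate(outs)
        return (out, np.concatenate(acts)) if keep is not None else out

    def predict(self, X) -> np.ndarray:
        """DLi-ASc (0-100) per clip."""
        check_is_fitted(self, "net_")
        out = self._forward_batched(list(X))
        return 100.0 * _sigmoid(out[:, 0])

    def predict_aux(self, X) -> np.ndarray:
        """Auxiliary (Vmax, mPG, AVA) predictions in raw units, (n, 3)."""
        check_is_fitted(self, "net_")
        out = self._forward_batched(list(X))
        return out[:, 1:4] * self.aux_std_ + self.aux_mean_

    def features(self, X) -> np.ndarray:
        """Penultimate activations, (n, 32)."""
        check_is_fitted(self, "net_")
        _, act = self._forward_batched(list(X), keep=self.penult_index_)
        return act

    # ---------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net_.state_dict(),
                 aux_mean=self.aux_mean_, aux_std=self.aux_std_)
        cfg = {k: getattr(self, k) for k in self.get_params()}
        (path / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ContinuumScorer":
        path = Path(path)
        cfg = json.loads((path / "config.json").read_text())
        scorer = cls(**cfg)
        data = np.load(path / "weights.npz")
        rng = np.random.default_rng(scorer.random_state)
        scorer.net_, scorer.cam_index_, scorer.penult_index_ = _build_video_net(rng)
        scorer.net_.load_state_dict({k: data[k] for k in data.files
                                     if k not in ("aux_mean", "aux_std")})
        scorer.aux_mean_ = data["aux_mean"]
        scorer.aux_std_ = data["aux_std"]
        scorer.history_ = []
        return scorer


def train_continuum_model(videos, labels, aux=None, aux_mask=None,
                          **params) -> ContinuumScorer:
    """Functional wrapper over :class:`ContinuumScorer`."""
    return ContinuumScorer(**params).fit(videos, labels, aux=aux, aux_mask=aux_mask)


def score_video(scorer: ContinuumScorer, video: EchoVideo) -> float:
    """DLi-ASc of one clip; PLAX and PSAX views only."""
    if isinstance(video, EchoVideo) and video.view not in ("plax", "psax"):
        raise ValueError(f"unsupported view {video.view!r}")
    return float(scorer.predict([video])[0])


def aggregate_patient(scores: Sequence[tuple]) -> PatientScore:
    """Patient-level DLi-ASc: mean per view type, then across view types."""
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one per-video score")
    per_view: dict[str, list] = {}
    for view, s in scores:
        per_view.setdefault(view, []).append(float(s))
    means = {v: float(np.mean(ss)) for v, ss in per_view.items()}
    return PatientScore(per_video=[(v, float(s)) for v, s in scores],
                        per_view_mean=means,
                        dli_asc=float(np.mean(list(means.values()))))


def derive_cutoffs(scores: Sequence[float], stages: Sequence[Stage]) -> CutoffSet:
    """Midpoints between consecutive per-stage mean scores.

    Every stage must be represented; otherwise the absent stages are named
    in the error.
    """
    scores = np.asarray(list(scores), dtype=float)
    stages = [Stage(s) for s in stages]
    means = {}
    for st in Stage:
        sel = [sc for sc, s in zip(scores, stages) if s == st]
        if sel:
            means[st] = float(np.mean(sel))
    missing = [st.name.lower() for st in Stage if st not in means]
    if missing:
        raise ValueError(f"cannot derive cutoffs; absent stages: {', '.join(missing)}")
    pairs = list(Stage)
    cuts = [(means[a] + means[b]) / 2.0 for a, b in zip(pairs, pairs[1:])]
    return CutoffSet(sclerosis=cuts[0], mild=cuts[1], moderate=cuts[2], severe=cuts[3])


def classify_by_cutoffs(score: float, cutoffs: CutoffSet = DEFAULT_CUTOFFS) -> Stage:
    """Stage of the highest cutoff at or below the score (inclusive)."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("score must lie in [0, 100]")
    stage = Stage.NORMAL
    for st, cut in zip((Stage.SCLEROSIS, Stage.MILD, Stage.MODERATE, Stage.SEVERE),
                       cutoffs.as_tuple()):
        if score >= cut:
            stage = st
    return stage


def saliency_map(scorer: ContinuumScorer, video: Union[EchoVideo, np.ndarray]
                 ) -> np.ndarray:
    """Grad-CAM-style saliency of the continuum head, per frame.

    The map is the gradient-weighted activation magnitude of the last
    convolutional stage, sum over channels of \\|dA * A\\| where dA is the
    gradient of the continuum logit with respect to the activation A.  The
    magnitude (rather than the signed, channel-pooled classic variant) is
    used because influence on a *continuum* output is informative in both
    directions: leaflet evidence that lowers the score of a mild case is
    still the region the model looked at.  The map is upsampled to the
    frame grid and max-normalised to [0, 1] (all zero when there is no
    response, e.g. for a constant clip).
    """
    check_is_fitted(scorer, "net_")
    frames = video.frames if isinstance(video, EchoVideo) else np.asarray(video)
    t, h, w = frames.shape
    xb = scorer._as_batch([video])
    out, act = scorer.net_.forward(xb, keep_activation=scorer.cam_index_)
    dout = np.zeros_like(out)
    dout[:, 0] = 1.0
    dact = scorer.net_.backward(dout, upto=scorer.cam_index_)
    cam = np.abs(dact * act).sum(axis=1)[0]                  # (T', h', w')
    zoom = (t / cam.shape[0], h / cam.shape[1], w / cam.shape[2])
    cam = np.maximum(ndimage.zoom(cam, zoom, order=1), 0.0)
    cam = cam[:t, :h, :w]
    if cam.max() > 0:
        cam = cam / cam.max()
    return cam


def embed_features(scorer: ContinuumScorer, videos, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Penultimate features and their 2D nonlinear projection.

    The projection uses 15 nearest neighbours, minimum distance 0.1 and the
    Euclidean metric, with a fixed seed for reproducibility.
    """
    videos = list(videos)
    if len(videos) < 16:
        raise ValueError("need at least 16 videos to embed")
    feats = scorer.features(videos)
    import umap

    reducer = umap.UMAP(n_neighbors=15, min_dist=0.1, metric="euclidean",
                        random_state=seed)
    emb = reducer.fit_transform(feats)
    return feats, np.asarray(emb, dtype=float)
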