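"""Desk-scale learned segmentation providers.

Two sklearn-style estimators wrap the same small fully-convolutional
encoder-decoder (stride-2 encoder, nearest-neighbour upsampling decoder,
Monte-Carlo dropout in the bottleneck):

* :class:`EnvelopeSegmenter` — binary spectral-Doppler envelope masks; the
  input channels are the intensity image and the signed velocity coordinate
  of each row relative to the baseline, so the learned rule transfers across
  spectrogram sizes.
* :class:`PlaxSegmenter` — 9-class PLAX anatomy maps; the input channels are
  the frame intensity plus normalised x/y coordinates (the anatomy phantoms
  have a stable layout, so coordinates carry most of the shape prior).

Both train with per-pixel softmax cross-entropy and Adam on phantom
(image, truth-mask) pairs.  ``predict_proba`` returns a (C, H, W) stack
summing to 1 per pixel; ``mc_probs`` returns stochastic dropout passes for
the uncertainty gate.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, Conv2d, Dropout, ReLU, Sequential, Upsample2x
from .datatypes import DopplerSpectrum, PlaxLabelMap

__all__ = ["EnvelopeSegmenter", "PlaxSegmenter", "dice_score"]


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, truth).sum() / denom


def _build_segnet(c_in: int, c_out: int, width: int, dropout: float, rng):
    return Sequential([
        Conv2d(c_in, width, 3, rng=rng), ReLU(),
        Conv2d(width, 2 * width, 3, stride=2, rng=rng), ReLU(),
        Dropout(dropout),
        Conv2d(2 * width, 2 * width, 3, rng=rng), ReLU(),
        Upsample2x(),
        Conv2d(2 * width, width, 3, rng=rng), ReLU(),
        Conv2d(width, c_out, 1, rng=rng),
    ])


def _softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _SegBase(BaseEstimator):
    """Shared training loop; subclasses define channels and targets."""

    _n_classes = 2

    def __init__(self, width=10, dropout=0.15, n_iter=250, batch_size=6,
                 lr=3e-3, random_state=0):
        self.width = width
        self.dropout = dropout
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    # subclasses: build (C_in, H, W) input stack from one raw item
    def _stack(self, item) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    #: optional per-class pixel weights for the cross-entropy (None = uniform)
    _class_weight: Optional[np.ndarray] = None

    def _fit_pairs(self, stacks, targets) -> "._SegBase":
        rng = np.random.default_rng(self.random_state)
        self.net_ = _build_segnet(stacks[0].shape[0], self._n_classes,
                                  self.width, self.dropout, rng)
        opt = Adam(self.net_, lr=self.lr)
        n = len(stacks)
        self.loss_history_ = []
        for it in range(self.n_iter):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb, yb = self._sample_batch(stacks, targets, idx, rng)
            logits = self.net_.forward(xb, train=True, rng=rng)
            probs = _softmax(logits, axis=1)
            onehot = np.zeros_like(probs)
            np.put_along_axis(onehot, yb[:, None], 1.0, axis=1)
            logp = np.log(np.take_along_axis(probs, yb[:, None], axis=1)[:, 0] + 1e-9)
            if self._class_weight is not None:
                wpix = self._class_weight[yb]
            else:
                wpix = np.ones_like(logp)
            wsum = wpix.sum()
            loss = -float((wpix * logp).sum() / wsum)
            self.net_.backward((probs - onehot) * (wpix[:, None] / wsum))
            opt.step()
            self.loss_history_.append(loss)
        return self

    def _sample_batch(self, stacks, targets, idx, rng):
        xb = np.stack([stacks[i] for i in idx])
        yb = np.stack([targets[i] for i in idx])
        return xb, yb

    def _forward_proba(self, stack: np.ndarray, train=False, rng=None) -> np.ndarray:
        check_is_fitted(self, "net_")
        h, w = stack.shape[1:]
        ph, pw = h % 2, w % 2
        x = np.pad(stack, ((0, 0), (0, ph), (0, pw)))[None]
        logits = self.net_.forward(x, train=train, rng=rng)
        probs = _softmax(logits, axis=1)[0, :, :h, :w]
        return probs.astype(np.float32)


class EnvelopeSegmenter(_SegBase):
    """Learned spectral-Doppler envelope segmenter (binary)."""

    _n_classes = 2

    def __init__(self, width=10, dropout=0.15, n_iter=250, batch_size=6,
                 lr=3e-3, crop_cols=64, random_state=0):
        super().__init__(width=width, dropout=dropout, n_iter=n_iter,
                         batch_size=batch_size, lr=lr, random_state=random_state)
        self.crop_cols = crop_cols

    def _stack(self, spectrum: DopplerSpectrum) -> np.ndarray:
        rows = np.arange(spectrum.intensity.shape[0], dtype=float)
        offset = (rows - spectrum.baseline_row) * spectrum.velocity_per_row
        if spectrum.flow_side == "above":
            offset = -offset
        coord = np.repeat(offset[:, None] / 6.0, spectrum.intensity.shape[1], axis=1)
        return np.stack([spectrum.intensity.astype(float), coord])

    def fit(self, X, y):
        """X: list of DopplerSpectrum; y: list of binary truth masks."""
        stacks = [self._stack(s) for s in X]
        targets = [np.asarray(m, dtype=int) for m in y]
        return self._fit_pairs(stacks, targets)

    def _sample_batch(self, stacks, targets, idx, rng):
        # random full-height column strips keep training cost flat in width
        xs, ys = [], []
        for i in idx:
            w = stacks[i].shape[2]
            cw = min(self.crop_cols, w)
            c0 = int(rng.integers(0, w - cw + 1))
            xs.append(stacks[i][:, :, c0:c0 + cw])
            ys.append(targets[i][:, c0:c0 + cw])
        return np.stack(xs), np.stack(ys)

    def predict_mask(self, spectrum: DopplerSpectrum) -> np.ndarray:
        """Foreground (envelope) probability map, shape (H, W)."""
        return self._forward_proba(self._stack(spectrum))[1]

    def predict_proba(self, spectrum: DopplerSpectrum) -> np.ndarray:
        return self._forward_proba(self._stack(spectrum))

    def mc_probs(self, spectrum: DopplerSpectrum, n_passes: int = 8,
                 seed: int = 0) -> list[np.ndarray]:
        stack = self._stack(spectrum)
        rng = np.random.default_rng(seed)
        return [self._forward_proba(stack, train=True, rng=rng)
                for _ in range(n_passes)]


class PlaxSegmenter(_SegBase):
    """Learned 9-class PLAX anatomy segmenter.

    Thin, rare structures (valve leaflets) are upweighted in the pixel
    cross-entropy so they are not drowned out by the large chambers.
    """

    _n_classes = 9
    _class_weight = np.array([0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 4.0])

    def _stack(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        h, w = frame.shape
        yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
        return np.stack([frame, xx, yy])

    def fit(self, X, y):
        """X: list of 2D frames in [0, 1]; y: list of integer label maps."""
        stacks = [self._stack(f) for f in X]
        targets = [np.asarray(m, dtype=int) for m in y]
        return self._fit_pairs(stacks, targets)

    def predict_proba(self, frame: np.ndarray) -> np.ndarray:
        return self._forward_proba(self._stack(frame))

    def predict_label_map(self, frame: np.ndarray, pixel_spacing: float) -> PlaxLabelMap:
        probs = self.predict_proba(frame)
        return PlaxLabelMap(labels=np.argmax(probs, axis=0), probabilities=probs,
                            pixel_spacing=pixel_spacing)

    def mc_probs(self, frame: np.ndarray, n_passes: int = 8,
                 seed: int = 0) -> list[np.ndarray]:
        stack = self._stack(frame)
        rng = np.random.default_rng(seed)
        return [self._forward_proba(stack, train=True, rng=rng)
                for _ in range(n_passes)]
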