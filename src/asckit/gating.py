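"""Predictive-entropy uncertainty quantification and the measurement gate.

The segmentation networks emit per-pixel class probabilities; their mean
per-pixel entropy (in nats) summarises how confident a mask is.  With
several stochastic forward passes (Monte-Carlo dropout) the entropy of the
mean map decomposes into

    predictive = aleatoric + epistemic

where aleatoric is the mean per-pass entropy (data noise the model is sure
about) and epistemic is the mutual information between prediction and model
draw (disagreement between passes).  The automated conventional pathway
halts when the predictive entropy reaches the gate threshold; the continuum
score is produced regardless.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import GateConfig, UncertaintyReport

__all__ = [
    "predictive_entropy",
    "mc_decompose",
    "gate_measurement",
    "binary_to_stack",
    "uncertainty_report",
    "calibrate_threshold",
]

_EPS = 1e-12


def binary_to_stack(p: np.ndarray) -> np.ndarray:
    """Lift a foreground-probability map (H, W) to a class stack (2, H, W)."""
    p = np.asarray(p, dtype=float)
    return np.stack([p, 1.0 - p])


def _validate_stack(prob_map: np.ndarray) -> np.ndarray:
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim < 2:
        raise ValueError("probability map must be (C, ...) with C classes first")
    s = prob_map.sum(axis=0)
    if np.max(np.abs(s - 1.0)) > 1e-5:
        raise ValueError("per-pixel probabilities must sum to 1")
    return prob_map


def predictive_entropy(prob_map: np.ndarray) -> float:
    """Mean per-pixel entropy (nats) of a class-probability stack (C, H, W)."""
    prob_map = _validate_stack(prob_map)
    h = -(prob_map * np.log(prob_map + _EPS)).sum(axis=0)
    return float(h.mean())


def mc_decompose(prob_maps: Sequence[np.ndarray]) -> tuple[float, float]:
    """(aleatoric, epistemic) from stochastic forward passes.

    aleatoric = mean over passes of the per-pass entropy; epistemic =
    entropy of the mean map minus aleatoric (the BALD mutual information).
    Both are means over pixels, in nats.
    """
    if len(prob_maps) < 1:
        raise ValueError("at least one forward pass is required")
    stacks = [_validate_stack(p) for p in prob_maps]
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("all passes must share one grid")
    aleatoric = float(np.mean([predictive_entropy(s) for s in stacks]))
    total = predictive_entropy(np.mean(stacks, axis=0))
    epistemic = max(total - aleatoric, 0.0)
    return aleatoric, epistemic


def gate_measurement(report: UncertaintyReport, config: GateConfig) -> str:
    """"halt" iff the predictive entropy reaches the threshold (inclusive)."""
    return "halt" if report.predictive_entropy >= config.entropy_threshold else "proceed"


def uncertainty_report(prob_maps: Sequence[np.ndarray],
                       config: GateConfig) -> UncertaintyReport:
    """Build a gated report from stochastic passes (one pass => epistemic 0)."""
    aleatoric, epistemic = mc_decompose(prob_maps)
    report = UncertaintyReport(predictive_entropy=aleatoric + epistemic,
                               aleatoric=aleatoric, epistemic=epistemic)
    report.gate = gate_measurement(report, config)
    return report


def calibrate_threshold(entropies: Sequence[float], percentile: float = 95.0,
                        margin: float = 1.05) -> float:
    """Gate threshold as a high percentile of reference (clean) entropies."""
    entropies = np.asarray(list(entropies), dtype=float)
    if entropies.size == 0:
        raise ValueError("need at least one reference entropy")
    return float(np.percentile(entropies, percentile) * margin)
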