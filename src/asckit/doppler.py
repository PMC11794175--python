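"""Spectral-Doppler envelope quantification: Vmax, mPG and VTI per cycle.

The chain is: spectrogram -> envelope probability map -> velocity trace ->
ejection windows -> per-window measurements.  Two envelope providers are
interchangeable: a deterministic intensity-threshold + largest-component
rule (the oracle used for end-to-end checks) and a small learned segmenter
(:class:`asckit.segmenters.EnvelopeSegmenter`).

Conventions: velocities are magnitudes from the baseline on the configured
flow side; mPG is the ejection-window time-average of the instantaneous
simplified-Bernoulli gradient 4 v(t)^2; VTI is the trapezoidal integral of
v(t) over the window, reported in cm.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import ASMeasurements, DopplerSpectrum, EjectionWindow, VelocityTrace

__all__ = [
    "segment_envelope",
    "trace_from_mask",
    "detect_ejection_windows",
    "measure_spectral",
    "measure_spectrum",
]


def segment_envelope(spectrum: DopplerSpectrum, threshold: Optional[float] = None
                     ) -> np.ndarray:
    """Deterministic envelope probability map (threshold + component filter).

    Pixels brighter than ``threshold`` (default: midpoint of the intensity
    range) are candidate envelope; connected components smaller than 20% of
    the largest one (speckle, stray noise) are dropped — each ejection cycle
    is its own component, so all cycles survive.  Kept pixels get
    probability 0.99, everything else 0.01.  A flat image yields an all-low
    map (no envelope).
    """
    img = spectrum.intensity
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-6:
        return np.full(img.shape, 0.01, dtype=np.float32)
    thr = threshold if threshold is not None else lo + 0.5 * (hi - lo)
    binary = img >= thr
    prob = np.full(img.shape, 0.01, dtype=np.float32)
    if binary.any():
        comp, n = ndimage.label(binary)
        sizes = ndimage.sum_labels(binary, comp, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= 0.2 * sizes.max()) + 1
        prob[np.isin(comp, keep)] = 0.99
    return prob


def trace_from_mask(mask: np.ndarray, spectrum: DopplerSpectrum) -> VelocityTrace:
    """Velocity trace from an envelope probability map.

    Per time column, the velocity is the furthest envelope pixel from the
    baseline on the flow side times the velocity calibration; columns with
    no envelope pixel read zero.  An entirely empty mask yields an all-zero
    trace flagged ``empty`` rather than an exception.
    """
    mask = np.asarray(mask)
    if mask.shape != spectrum.intensity.shape:
        raise ValueError("mask and spectrum grids differ")
    binary = mask >= 0.5
    rows = np.arange(mask.shape[0])[:, None]
    offset = (rows - spectrum.baseline_row if spectrum.flow_side == "below"
              else spectrum.baseline_row - rows)
    offset = np.where(binary & (offset > 0), offset, 0)
    depth = offset.max(axis=0)
    times = (np.arange(mask.shape[1]) + 0.5) * spectrum.time_per_col
    velocities = depth * spectrum.velocity_per_row
    return VelocityTrace(times=times, velocities=velocities, empty=not binary.any())


def detect_ejection_windows(trace: VelocityTrace, threshold_frac: float = 0.15,
                            min_duration: float = 0.1) -> list[EjectionWindow]:
    """Ejection windows around maximal runs with v >= threshold_frac * Vmax.

    The threshold identifies candidate cycles; each run is then expanded
    outward to the surrounding zero-velocity boundary so the window covers
    the full ejection support (otherwise time-averaged quantities such as
    mPG would be biased by the missing low-velocity tails).  Runs whose
    above-threshold part is shorter than ``min_duration`` seconds are
    discarded.  An all-zero trace yields no windows.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    v = trace.velocities
    if v.size == 0 or v.max() <= 0:
        return []
    above = v >= threshold_frac * v.max()
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(v.size)
    windows = []
    prev_end = -1
    for s, e in zip(starts, ends):
        if trace.times[e - 1] - trace.times[s] < min_duration:
            continue
        while s > prev_end + 1 and v[s - 1] > 0:
            s -= 1
        while e < v.size and v[e] > 0:
            e += 1
        # include the bounding zero samples so the trapezoid covers the
        # closed support and time averages use the full ejection duration
        if s > prev_end + 1 and v[s - 1] == 0:
            s -= 1
        if e < v.size and v[e] == 0:
            e += 1
        prev_end = e - 1
        windows.append(EjectionWindow(start=float(trace.times[s]),
                                      end=float(trace.times[e - 1])))
    return windows


def measure_spectral(trace: VelocityTrace, windows: Sequence[EjectionWindow],
                     policy: str = "mean") -> tuple[float, float, float]:
    """Aggregate (Vmax m/s, mPG mmHg, VTI cm) over ejection windows.

    Per window: Vmax is the peak of v(t); mPG the time-average of 4 v(t)^2;
    VTI the trapezoidal integral of v(t), in cm.  Across windows, ``mean``
    averages mPG and VTI while Vmax is always the global maximum; ``max``
    takes the maximum of each.
    """
    if policy not in ("mean", "max"):
        raise ValueError("policy must be 'mean' or 'max'")
    if not windows:
        raise ValueError("at least one ejection window is required")
    vmaxs, mpgs, vtis = [], [], []
    for w in windows:
        sel = (trace.times >= w.start) & (trace.times <= w.end)
        if sel.sum() < 2:
            continue
        t, v = trace.times[sel], trace.velocities[sel]
        vmaxs.append(float(v.max()))
        mpgs.append(float(np.trapezoid(4.0 * v ** 2, t) / (t[-1] - t[0])))
        vtis.append(float(np.trapezoid(v, t) * 100.0))
    if not vmaxs:
        raise ValueError("no window contained enough samples")
    agg = np.mean if policy == "mean" else np.max
    return float(np.max(vmaxs)), float(agg(mpgs)), float(agg(vtis))


def measure_spectrum(spectrum: DopplerSpectrum, mask: Optional[np.ndarray] = None,
                     policy: str = "mean", threshold_frac: float = 0.15,
                     min_duration: float = 0.1) -> ASMeasurements:
    """Full chain on one spectrogram; unavailable fields stay ``None``.

    Uses the deterministic envelope provider when no mask is supplied.  The
    AV CW jet fills vmax/mpg/av_vti; an LVOT PW trace fills lvot_vti.
    """
    if mask is None:
        mask = segment_envelope(spectrum)
    trace = trace_from_mask(mask, spectrum)
    windows = detect_ejection_windows(trace, threshold_frac, min_duration)
    if not windows:
        return ASMeasurements()
    vmax, mpg, vti = measure_spectral(trace, windows, policy)
    if spectrum.view_tag == "lvot_pw":
        return ASMeasurements(lvot_vti=vti)
    return ASMeasurements(vmax=vmax, mpg=mpg, av_vti=vti)
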