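"""PLAX anatomy measurement: LVOT diameter and calcification readout.

The LVOT diameter is measured on a label map at mid-systole: the annulus is
localised as the contact line between the LV and aorta classes, its
orientation taken from the principal axis of the contact pixels, and the
diameter read inner-edge to inner-edge as the length of the lumen run
(LV / aorta / valve classes) along that line.  Over a clip, the reported
value is the median over the three most-open frames.  The measurement is
purely geometric, so it works identically on truth label maps (the oracle
provider) and on learned segmentations.

The annulus is measured at the LV-aorta junction itself; ``offset_cm``
shifts the measurement plane into the LVOT for conventions that measure
slightly below the valve.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .datatypes import EchoVideo, LinearMeasurement, PlaxLabelMap, PLAX_CLASSES
from .phantoms import PhantomTruth, leaflet_opening_gap
from .segmenters import PlaxSegmenter

__all__ = [
    "segment_plax",
    "label_maps_from_truth",
    "select_midsystolic_frame",
    "measure_lvot_diameter",
    "detect_calcification",
]

_LUMEN = (PLAX_CLASSES["lv"], PLAX_CLASSES["aorta"], PLAX_CLASSES["av"],
          PLAX_CLASSES["mv"])


def segment_plax(video: EchoVideo, segmenter: PlaxSegmenter) -> list[PlaxLabelMap]:
    """Per-frame anatomy maps of a PLAX clip from a trained segmenter."""
    if video.view != "plax":
        raise ValueError(f"segment_plax requires a PLAX clip, got view={video.view!r}")
    return [segmenter.predict_label_map(f, video.pixel_spacing) for f in video.frames]


def label_maps_from_truth(truth: PhantomTruth, pixel_spacing: float
                          ) -> list[PlaxLabelMap]:
    """Oracle provider: wrap generator truth label maps as certain maps."""
    return [PlaxLabelMap.from_labels(lab, pixel_spacing)
            for lab in truth.label_map_truth]


def _gaps(maps: Sequence[PlaxLabelMap]) -> np.ndarray:
    return np.array([leaflet_opening_gap(m.labels, m.pixel_spacing) for m in maps])


def select_midsystolic_frame(maps: Sequence[PlaxLabelMap]) -> int:
    """Index of the frame with the widest aortic-valve opening.

    Ties break to the lowest index.  Raises when no frame contains any
    valve pixels (unmeasurable study).
    """
    if not maps:
        raise ValueError("need at least one frame")
    if not any((m.labels == PLAX_CLASSES["av"]).any() for m in maps):
        raise ValueError("no aortic-valve pixels in any frame; study unmeasurable")
    return int(np.argmax(_gaps(maps)))


def _measure_single(m: PlaxLabelMap, offset_cm: float, frame_index: int
                    ) -> LinearMeasurement:
    lab = m.labels
    lv = lab == PLAX_CLASSES["lv"]
    ao = lab == PLAX_CLASSES["aorta"]
    if not lv.any() or not ao.any():
        missing = "LV" if not lv.any() else "aorta"
        raise ValueError(f"label map lacks the {missing} class; unmeasurable")

    # contact pixels: LV pixels 4-adjacent to aorta, and vice versa
    ao_dil = ndimage.binary_dilation(ao)
    lv_dil = ndimage.binary_dilation(lv)
    contact = (lv & ao_dil) | (ao & lv_dil)
    if not contact.any():
        raise ValueError("LV and aorta never touch; annulus not localisable")

    pts = np.argwhere(contact).astype(float)          # (n, 2) rows, cols
    centroid = pts.mean(axis=0)
    if len(pts) == 1:
        axis = np.array([1.0, 0.0])
    else:
        _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        axis = vt[0] / np.linalg.norm(vt[0])          # annulus direction

    if offset_cm:
        # shift the plane along the outflow axis (perpendicular, towards LV)
        normal = np.array([-axis[1], axis[0]])
        lv_c = np.argwhere(lv).mean(axis=0)
        if np.dot(lv_c - centroid, normal) < 0:
            normal = -normal
        centroid = centroid + normal * (offset_cm / m.pixel_spacing)

    # walk the annulus line and take the lumen run through the centroid
    h, w = lab.shape
    step = 0.5
    smax = int(np.hypot(h, w) / step)
    lumen_run = {}
    for sgn in (1.0, -1.0):
        s = 0.0
        while s <= smax * step:
            p = centroid + sgn * s * axis
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < h and 0 <= c < w) or lab[r, c] not in _LUMEN:
                break
            lumen_run[sgn] = s
            s += step
    if not lumen_run:
        raise ValueError("annulus centroid does not sit in the lumen")
    s_pos = lumen_run.get(1.0, 0.0)
    s_neg = lumen_run.get(-1.0, 0.0)
    # +1 px: the run counts pixel centres, the edges sit half a pixel beyond
    length_px = s_pos + s_neg + 1.0
    p0 = tuple(np.round(centroid - s_neg * axis).astype(int))
    p1 = tuple(np.round(centroid + s_pos * axis).astype(int))
    return LinearMeasurement(value=float(length_px * m.pixel_spacing),
                             endpoints=(p0, p1), frame_index=frame_index)


def measure_lvot_diameter(maps: Union[PlaxLabelMap, Sequence[PlaxLabelMap]],
                          offset_cm: float = 0.0) -> LinearMeasurement:
    """LVOT diameter (cm) from one label map or a clip of maps.

    Given a sequence, the three most-open frames are measured and the
    median value reported (with the endpoints of the median frame).
    """
    if isinstance(maps, PlaxLabelMap):
        return _measure_single(maps, offset_cm, 0)
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one label map")
    order = np.argsort(-_gaps(maps), kind="stable")[:3]
    meas = [_measure_single(maps[i], offset_cm, int(i)) for i in order]
    values = [mm.value for mm in meas]
    med = int(np.argsort(values)[len(values) // 2])
    out = meas[med]
    out.value = float(np.median(values))
    return out


def detect_calcification(video: EchoVideo, maps: Sequence[PlaxLabelMap],
                         threshold: float = 0.75) -> Optional[bool]:
    """Brightness-based calcification readout of the aortic valve.

    Mean image intensity over valve-class pixels, compared against a fixed
    threshold; returns ``None`` when no valve pixels are found.
    """
    vals = []
    for frame, m in zip(video.frames, maps):
        av = m.labels == PLAX_CLASSES["av"]
        if av.any():
            vals.append(float(frame[av].mean()))
    if not vals:
        return None
    return bool(np.mean(vals) >= threshold)
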