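"""Study-bundle serialisation.

One directory per patient::

    P0000/
      sidecar.json            # views, calibrations, seed, optional truth
      video_plax.npz          # frames (T, H, W) float32
      video_psax.npz
      spectrum_av_cw.npz      # intensity image
      spectrum_lvot_pw.npz
      spectrum_av_cw.png      # 8-bit preview
      labels/frame_000.png    # 8-bit PLAX truth label maps (when present)

The sidecar carries every physical calibration; reading a bundle without a
required calibration raises a parse error naming the missing field.  JSON is
written with sorted keys so a write -> read -> write round trip is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .datatypes import ASMeasurements, DopplerSpectrum, EchoVideo, Stage

__all__ = ["StudyBundle", "write_bundle", "read_bundle", "read_dicom_video"]


@dataclass
class StudyBundle:
    """Per-patient inputs for the dual pathway (plus optional ground truth)."""

    patient_id: str
    videos: list = field(default_factory=list)       # EchoVideo
    spectra: list = field(default_factory=list)      # DopplerSpectrum
    truth_measurements: Optional[ASMeasurements] = None
    truth_stage: Optional[Stage] = None
    truth_label_maps: Optional[np.ndarray] = None    # (T, H, W) int PLAX labels

    def __post_init__(self) -> None:
        if not self.videos and not self.spectra:
            raise ValueError("a study bundle needs at least one video or spectrum")
        for v in self.videos:
            if v.view not in ("plax", "psax"):
                raise ValueError(f"unsupported view tag {v.view!r}")


def _spectrum_meta(s: DopplerSpectrum) -> dict:
    return {
        "velocity_per_row": s.velocity_per_row, "time_per_col": s.time_per_col,
        "baseline_row": s.baseline_row, "flow_side": s.flow_side,
        "modality": s.modality, "view_tag": s.view_tag,
    }


def write_bundle(path, bundle: StudyBundle) -> Path:
    """Write a bundle directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"patient_id": bundle.patient_id, "videos": [], "spectra": []}
    for v in bundle.videos:
        name = f"video_{v.view}"
        np.savez_compressed(path / f"{name}.npz", frames=v.frames)
        meta["videos"].append({"file": f"{name}.npz", "view": v.view,
                               "frame_rate": v.frame_rate,
                               "pixel_spacing": v.pixel_spacing})
    for s in bundle.spectra:
        name = f"spectrum_{s.view_tag}"
        np.savez_compressed(path / f"{name}.npz", intensity=s.intensity)
        iio.imwrite(path / f"{name}.png",
                    (np.clip(s.intensity, 0, 1) * 255).astype(np.uint8))
        meta["spectra"].append({"file": f"{name}.npz", **_spectrum_meta(s)})
    if bundle.truth_measurements is not None:
        m = bundle.truth_measurements
        meta["truth_measurements"] = {
            k: getattr(m, k) for k in ("vmax", "mpg", "ava", "av_vti",
                                       "lvot_vti", "lvot_diameter", "calcified")}
    if bundle.truth_stage is not None:
        meta["truth_stage"] = Stage(bundle.truth_stage).name.lower()
    if bundle.truth_label_maps is not None:
        lab_dir = path / "labels"
        lab_dir.mkdir(exist_ok=True)
        for i, lab in enumerate(bundle.truth_label_maps):
            iio.imwrite(lab_dir / f"frame_{i:03d}.png", lab.astype(np.uint8))
        meta["n_label_frames"] = int(len(bundle.truth_label_maps))
    (path / "sidecar.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def _require(d: dict, key: str, context: str):
    if key not in d:
        raise ValueError(f"bundle sidecar is missing {key!r} for {context}")
    return d[key]


def read_bundle(path) -> StudyBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    sidecar = path / "sidecar.json"
    if not sidecar.exists():
        raise ValueError(f"missing sidecar.json in {path}")
    meta = json.loads(sidecar.read_text())
    pid = _require(meta, "patient_id", str(path))
    videos = []
    for vm in meta.get("videos", []):
        frames = np.load(path / _require(vm, "file", "video"))["frames"]
        videos.append(EchoVideo(
            frames=frames, view=_require(vm, "view", "video"),
            frame_rate=_require(vm, "frame_rate", "video"),
            pixel_spacing=_require(vm, "pixel_spacing", "video"),
            patient_id=pid))
    spectra = []
    for sm in meta.get("spectra", []):
        intensity = np.load(path / _require(sm, "file", "spectrum"))["intensity"]
        spectra.append(DopplerSpectrum(
            intensity=intensity,
            velocity_per_row=_require(sm, "velocity_per_row", "spectrum"),
            time_per_col=_require(sm, "time_per_col", "spectrum"),
            baseline_row=_require(sm, "baseline_row", "spectrum"),
            flow_side=sm.get("flow_side", "below"),
            modality=sm.get("modality", "CW"),
            view_tag=sm.get("view_tag", "av_cw"),
            patient_id=pid))
    truth_m = None
    if "truth_measurements" in meta:
        truth_m = ASMeasurements(**meta["truth_measurements"])
    truth_stage = None
    if "truth_stage" in meta:
        truth_stage = Stage[meta["truth_stage"].upper()]
    labels = None
    if meta.get("n_label_frames"):
        labels = np.stack([
            iio.imread(path / "labels" / f"frame_{i:03d}.png")
            for i in range(meta["n_label_frames"])]).astype(np.int8)
    return StudyBundle(patient_id=pid, videos=videos, spectra=spectra,
                       truth_measurements=truth_m, truth_stage=truth_stage,
                       truth_label_maps=labels)


def read_dicom_video(path, view: str = "plax") -> EchoVideo:
    """Optional single-file DICOM import mapped onto the video container.

    Uses frame time and pixel spacing tags when present; defaults otherwise.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # RGB -> gray
        arr = arr.mean(axis=-1)
    arr = (arr - arr.min()) / max(arr.max() - arr.min(), 1e-9)
    frame_time_ms = float(getattr(ds, "FrameTime", 33.3))
    spacing = float(getattr(ds, "PixelSpacing", [0.05, 0.05])[0])
    return EchoVideo(frames=arr, view=view, frame_rate=1000.0 / frame_time_ms,
                     pixel_spacing=spacing, patient_id=str(getattr(ds, "PatientID", "")))
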