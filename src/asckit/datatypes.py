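"""Core domain containers shared across the toolkit.

Everything downstream of the generator speaks in these types: grayscale echo
videos with physical calibration, spectral-Doppler spectrograms with axis
calibration, measurement records with explicit availability, and staging
results.  Measurements use ``None`` for "not available"; a halted or failed
measurement is always ``None``, never a sentinel number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Stage",
    "StageFlag",
    "EchoVideo",
    "DopplerSpectrum",
    "VelocityTrace",
    "EjectionWindow",
    "ASMeasurements",
    "ASStage",
    "PlaxLabelMap",
    "LinearMeasurement",
    "PatientScore",
    "CutoffSet",
    "UncertaintyReport",
    "GateConfig",
    "PLAX_CLASSES",
]


class Stage(enum.IntEnum):
    """Aortic stenosis severity stages, ordered along the disease continuum."""

    NORMAL = 0
    SCLEROSIS = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4

    @property
    def ordinal(self) -> int:
        return int(self)


class StageFlag(enum.Enum):
    """Qualifiers attached to a staging result."""

    MILD_TO_MODERATE = "mild_to_moderate"
    MODERATE_TO_SEVERE = "moderate_to_severe"
    LFLG_SEVERE_PATTERN = "lflg_severe_pattern"
    INSUFFICIENT_DATA = "insufficient_data"


#: Anatomical classes for PLAX segmentation label maps (fixed integer codes).
PLAX_CLASSES = {
    "background": 0,
    "lv": 1,
    "septum": 2,
    "posterior_wall": 3,
    "la": 4,
    "rv": 5,
    "aorta": 6,
    "mv": 7,
    "av": 8,
}


@dataclass
class EchoVideo:
    """A grayscale echo-like clip with physical calibration.

    frames : float array, shape (T, H, W), values in [0, 1]
    view : "plax" or "psax"
    frame_rate : frames per second
    pixel_spacing : cm per pixel (isotropic)
    """

    frames: np.ndarray
    view: str
    frame_rate: float
    pixel_spacing: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frame_rate <= 0 or self.pixel_spacing <= 0:
            raise ValueError("frame_rate and pixel_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape


@dataclass
class DopplerSpectrum:
    """Spectral-Doppler spectrogram with axis calibration.

    Rows are velocity bins, columns time bins.  ``baseline_row`` is the row
    of zero velocity; flow fills rows away from it on ``flow_side``
    ("below" = increasing row index).
    """

    intensity: np.ndarray
    velocity_per_row: float
    time_per_col: float
    baseline_row: int
    flow_side: str = "below"
    modality: str = "CW"
    view_tag: str = "av_cw"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D image")
        if self.velocity_per_row <= 0 or self.time_per_col <= 0:
            raise ValueError("axis calibrations must be positive")
        if not (0 <= self.baseline_row < self.intensity.shape[0]):
            raise ValueError("baseline_row must lie inside the image")
        if self.flow_side not in ("above", "below"):
            raise ValueError("flow_side must be 'above' or 'below'")


@dataclass
class VelocityTrace:
    """Velocity magnitude versus time, sampled at spectrogram columns."""

    times: np.ndarray
    velocities: np.ndarray
    empty: bool = False  # True when derived from an empty envelope mask

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.times.shape != self.velocities.shape:
            raise ValueError("times and velocities must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")


@dataclass(frozen=True)
class EjectionWindow:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ASMeasurements:
    """Conventional AS parameters; ``None`` marks an unavailable value."""

    vmax: Optional[float] = None          # m/s
    mpg: Optional[float] = None           # mmHg
    ava: Optional[float] = None           # cm^2
    av_vti: Optional[float] = None        # cm
    lvot_vti: Optional[float] = None      # cm
    lvot_diameter: Optional[float] = None  # cm
    calcified: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("vmax", "mpg", "ava", "av_vti", "lvot_vti", "lvot_diameter"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name} must be finite and >= 0, got {v}")
                setattr(self, name, v)
        if self.ava is not None and self.ava <= 0:
            raise ValueError("ava must be > 0 when available")

    def available(self) -> list[str]:
        return [
            k
            for k in ("vmax", "mpg", "ava", "av_vti", "lvot_vti", "lvot_diameter")
            if getattr(self, k) is not None
        ]

    def replace(self, **kw) -> "ASMeasurements":
        return replace(self, **kw)


@dataclass
class ASStage:
    """Result of guideline staging.

    ``stage is None`` means indeterminate (discordant bands or not enough
    data) and is never concordant; recognised discordance patterns carry
    flags (unnamed patterns, e.g. Vmax-mild against AVA-moderate, may not).
    ``concordant`` is True only when every available parameter agreed.
    """

    stage: Optional[Stage]
    concordant: bool
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.flags = frozenset(self.flags)
        if self.concordant and self.flags:
            raise ValueError("a concordant stage carries no flags")
        if self.stage is None and self.concordant:
            raise ValueError("an indeterminate stage cannot be concordant")


@dataclass
class PlaxLabelMap:
    """Per-pixel anatomical classes for one PLAX frame.

    ``labels`` is the argmax of ``probabilities`` (C, H, W); probabilities sum
    to 1 per pixel.
    """

    labels: np.ndarray
    probabilities: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float32)
        if self.probabilities.ndim != 3:
            raise ValueError("probabilities must be (C, H, W)")
        if self.labels.shape != self.probabilities.shape[1:]:
            raise ValueError("labels and probabilities grids differ")
        s = self.probabilities.sum(axis=0)
        if np.max(np.abs(s - 1.0)) > 1e-4:
            raise ValueError("probabilities must sum to 1 per pixel")
        if not np.array_equal(self.labels, np.argmax(self.probabilities, axis=0)):
            raise ValueError("labels must be the argmax of probabilities")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @classmethod
    def from_labels(cls, labels: np.ndarray, pixel_spacing: float,
                    n_classes: int = 9) -> "PlaxLabelMap":
        """Build a one-hot (certain) label map from an integer label image."""
        labels = np.asarray(labels, dtype=int)
        probs = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
        for c in range(n_classes):
            probs[c][labels == c] = 1.0
        return cls(labels=labels, probabilities=probs, pixel_spacing=pixel_spacing)


@dataclass
class LinearMeasurement:
    """A caliper measurement on one frame, in physical units."""

    value: float          # cm
    endpoints: tuple      # ((row, col), (row, col))
    frame_index: int


@dataclass
class PatientScore:
    """DLi-ASc aggregation: per-video scores, per-view means, final score."""

    per_video: list          # [(view, score), ...]
    per_view_mean: dict      # view -> mean score
    dli_asc: float


@dataclass
class CutoffSet:
    """DLi-ASc severity thresholds (0-100), strictly increasing."""

    sclerosis: float
    mild: float
    moderate: float
    severe: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(not 0 <= v <= 100 for v in vals):
            raise ValueError("cutoffs must lie in [0, 100]")
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ValueError("cutoffs must be strictly increasing")

    def as_tuple(self) -> tuple:
        return (self.sclerosis, self.mild, self.moderate, self.severe)


@dataclass
class UncertaintyReport:
    """Predictive-entropy decomposition for one segmentation output."""

    predictive_entropy: float  # nats, mean over pixels
    aleatoric: float
    epistemic: float
    gate: str = "proceed"      # "proceed" | "halt"

    def __post_init__(self) -> None:
        if min(self.predictive_entropy, self.aleatoric, self.epistemic) < -1e-9:
            raise ValueError("entropies must be non-negative")
        if abs(self.predictive_entropy - (self.aleatoric + self.epistemic)) > 1e-6:
            raise ValueError("predictive entropy must equal aleatoric + epistemic")


@dataclass
class GateConfig:
    """Gate threshold (nats) and Monte-Carlo sample count."""

    entropy_threshold: float = 0.15
    mc_samples: int = 8

    def __post_init__(self) -> None:
        if self.entropy_threshold <= 0:
            raise ValueError("entropy_threshold must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
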