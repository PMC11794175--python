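"""Seeded synthetic echo phantoms with analytic ground truth.

The generator emulates, at desk scale, the inputs an AS evaluation system
sees: PLAX / PSAX grayscale clips in which the aortic-valve leaflets open
less (and look brighter when calcified) as severity progresses, spectral
Doppler spectrograms whose envelope follows a half-sine ejection profile,
and cohort tables with stage-concordant conventional parameters.

Generative identities (the analytic oracle for every measurement stage):

* ejection profile  v(t) = Vmax sin(pi t / T_ej)  within each ejection window
* VTI   = (2/pi) Vmax T_ej * 100          [cm; integral of the half-sine]
* mPG   = 2 Vmax^2                        [mmHg; ejection-window mean of the
                                           simplified Bernoulli 4 v(t)^2]
* AVA   = pi (D/2)^2 VTI_LVOT / VTI_AV    [cm^2; continuity equation]

The mPG identity is a generator convention (half-sine + Bernoulli), not a
physiological claim.  It couples mPG to Vmax, so cohort sampling draws Vmax
from sub-bands whose implied mPG falls in the same severity band — otherwise
the spec would be internally discordant, and discordant ground truth is
exactly what consistent labelling excludes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import ASMeasurements, DopplerSpectrum, EchoVideo, Stage, VelocityTrace
from .staging import compute_ava_continuity

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DopplerCalibration",
    "sample_cohort",
    "render_views",
    "render_doppler",
    "analytic_truth",
    "envelope_truth_mask",
    "leaflet_opening_gap",
    "cohort_table",
    "FOV_CM",
]

#: physical field of view of rendered frames (cm, square)
FOV_CM = 6.4

#: full Table-1 Vmax bands per stage (validation bounds)
STAGE_VMAX_BAND = {
    Stage.NORMAL: (1.0, 2.0),
    Stage.SCLEROSIS: (1.0, 2.0),
    Stage.MILD: (2.0, 3.0),
    Stage.MODERATE: (3.0, 4.0),
    Stage.SEVERE: (4.0, 5.5),
}

# Sampling sub-bands.  Because the generator ties mPG to Vmax (mPG = 2 Vmax^2),
# moderate draws start above sqrt(10) ~ 3.162 m/s (mPG >= 20) and severe above
# sqrt(20) ~ 4.472 m/s (mPG >= 40); margins also absorb the <= 1-row Doppler
# quantisation so noiseless end-to-end staging stays concordant.
_SAMPLE_VMAX = {
    Stage.NORMAL: (1.05, 1.95),
    Stage.SCLEROSIS: (1.05, 1.95),
    Stage.MILD: (2.05, 2.85),
    Stage.MODERATE: (3.20, 3.85),
    Stage.SEVERE: (4.55, 5.40),
}

# Target AVA bands, kept away from the 1.0 / 1.5 cm^2 boundaries so that the
# propagated error of a +-1-2 px LVOT-diameter measurement cannot flip bands.
_SAMPLE_AVA = {
    Stage.NORMAL: (2.2, 3.2),
    Stage.SCLEROSIS: (2.2, 3.2),
    Stage.MILD: (1.70, 2.60),
    Stage.MODERATE: (1.10, 1.42),
    Stage.SEVERE: (0.55, 0.95),
}

#: peak leaflet-opening fraction per stage ordinal (strictly decreasing)
_OPENING_MAX = (1.00, 0.82, 0.64, 0.46, 0.28)

_LEAFLET_PLAIN = 0.55
_LEAFLET_CALCIFIED = 0.92


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic patient."""

    patient_id: str
    true_stage: Stage
    true_vmax: float            # m/s
    ejection_duration: float    # s
    heart_rate: float           # beats/min
    true_lvot_diameter: float   # cm
    true_lvot_vti: float        # cm
    calcified: bool
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_stage = Stage(self.true_stage)
        lo, hi = STAGE_VMAX_BAND[self.true_stage]
        in_band = (self.true_vmax >= 4.0 if self.true_stage == Stage.SEVERE
                   else lo <= self.true_vmax < hi)
        if not in_band:
            raise ValueError(
                f"true_vmax {self.true_vmax} outside the {self.true_stage.name} band {lo}-{hi}")
        if self.calcified != (self.true_stage >= Stage.SCLEROSIS):
            raise ValueError("calcified must be true iff stage >= sclerosis")
        for name in ("true_vmax", "ejection_duration", "heart_rate",
                     "true_lvot_diameter", "true_lvot_vti"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ejection_duration >= 60.0 / self.heart_rate:
            raise ValueError("ejection_duration must be shorter than the cycle")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must lie in [0, 1]")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def true_av_vti(self) -> float:
        return (2.0 / math.pi) * self.true_vmax * self.ejection_duration * 100.0

    @property
    def true_ava(self) -> float:
        return compute_ava_continuity(
            self.true_lvot_diameter, self.true_lvot_vti, self.true_av_vti)


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a rendered phantom."""

    measurements: ASMeasurements
    label_map_truth: np.ndarray              # (T, H, W) int PLAX class labels
    psax_label_map_truth: np.ndarray         # (T, H, W) int PSAX class labels
    leaflet_box: dict                        # view -> (r0, c0, r1, c1) inclusive-exclusive
    peak_frame: int                          # frame of maximal leaflet opening
    opening: np.ndarray                      # per-frame opening fraction in [0, 1]


@dataclass
class DopplerCalibration:
    """Axis calibration of rendered spectrograms."""

    velocity_per_row: float = 0.02   # m/s per row
    time_per_col: float = 1.0 / 256  # s per column
    baseline_row: int = 8
    n_rows: int = 320
    flow_side: str = "below"

    def __post_init__(self) -> None:
        if self.velocity_per_row <= 0 or self.time_per_col <= 0:
            raise ValueError("calibration scales must be positive")
        if not 0 <= self.baseline_row < self.n_rows:
            raise ValueError("baseline_row must lie inside the image")


def analytic_truth(spec: PhantomSpec) -> ASMeasurements:
    """Closed-form conventional measurements implied by a spec."""
    return ASMeasurements(
        vmax=spec.true_vmax,
        mpg=2.0 * spec.true_vmax ** 2,
        ava=spec.true_ava,
        av_vti=spec.true_av_vti,
        lvot_vti=spec.true_lvot_vti,
        lvot_diameter=spec.true_lvot_diameter,
        calcified=spec.calcified,
    )


def _stage_counts(n: int, class_mix: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of n patients over the five stages."""
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (5,):
        raise ValueError("class_mix must have five entries")
    if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-6:
        raise ValueError("class_mix must be non-negative and sum to 1")
    raw = n * mix
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() == n:
            break
        counts[i] += 1
    return counts


def sample_cohort(n: int, class_mix: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2),
                  seed: int = 0, noise_level: float = 0.3) -> list[PhantomSpec]:
    """Draw a reproducible cohort of stage-concordant phantom specs.

    Stage counts follow ``class_mix`` up to largest-remainder rounding; Vmax
    is uniform inside the stage sampling band and the LVOT VTI is solved so
    the continuity-equation AVA lands in the stage-concordant band.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = _stage_counts(n, class_mix)
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    idx = 0
    for stage, count in zip(Stage, counts):
        for _ in range(count):
            vlo, vhi = _SAMPLE_VMAX[stage]
            alo, ahi = _SAMPLE_AVA[stage]
            vmax = rng.uniform(vlo, vhi)
            ava = rng.uniform(alo, ahi)
            hr = rng.uniform(60.0, 85.0)
            t_ej = rng.uniform(0.26, 0.32)
            d = rng.uniform(1.9, 2.3)
            av_vti = (2.0 / math.pi) * vmax * t_ej * 100.0
            lvot_vti = ava * av_vti / (math.pi * (d / 2.0) ** 2)
            specs.append(PhantomSpec(
                patient_id=f"P{idx:04d}",
                true_stage=stage,
                true_vmax=vmax,
                ejection_duration=t_ej,
                heart_rate=hr,
                true_lvot_diameter=d,
                true_lvot_vti=lvot_vti,
                calcified=stage >= Stage.SCLEROSIS,
                noise_level=noise_level,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            ))
            idx += 1
    return specs


def cohort_table(specs: Sequence[PhantomSpec]):
    """Ground-truth cohort table (one row per patient)."""
    import pandas as pd

    rows = []
    for s in specs:
        t = analytic_truth(s)
        rows.append({
            "patient_id": s.patient_id, "stage": s.true_stage.name.lower(),
            "vmax": t.vmax, "mpg": t.mpg, "ava": t.ava, "av_vti": t.av_vti,
            "lvot_vti": t.lvot_vti, "lvot_diameter": t.lvot_diameter,
            "calcified": s.calcified, "seed": s.seed,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# rendering helpers (all geometry in cm on the FOV_CM x FOV_CM grid)
# --------------------------------------------------------------------------

def _grid(resolution: int):
    spacing = FOV_CM / resolution
    c = (np.arange(resolution) + 0.5) * spacing
    Y, X = np.meshgrid(c, c, indexing="ij")
    return X, Y, spacing


def _segment_mask(X, Y, p0, p1, thickness):
    """Pixels within thickness/2 of the segment p0-p1 (points in cm, (x, y))."""
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = dx * dx + dy * dy
    if L2 == 0:
        d2 = (X - p0[0]) ** 2 + (Y - p0[1]) ** 2
    else:
        t = np.clip(((X - p0[0]) * dx + (Y - p0[1]) * dy) / L2, 0.0, 1.0)
        d2 = (X - p0[0] - t * dx) ** 2 + (Y - p0[1] - t * dy) ** 2
    return d2 <= (thickness / 2.0) ** 2


def _opening_curve(spec: PhantomSpec, n_frames: int) -> np.ndarray:
    """Per-frame leaflet opening fraction over one cardiac cycle."""
    o_max = _OPENING_MAX[spec.true_stage.ordinal]
    cycle = spec.cycle_duration
    t = np.arange(n_frames) * cycle / n_frames
    t_s = 0.08 * cycle
    phase = (t - t_s) / spec.ejection_duration
    o = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    return o_max * o


def _render_plax_frame(spec: PhantomSpec, X, Y, opening: float):
    """One PLAX frame: (intensity image, integer label map)."""
    cy, x0 = 3.1, 3.7
    D = spec.true_lvot_diameter
    img = np.full(X.shape, 0.18, dtype=np.float32)
    lab = np.zeros(X.shape, dtype=np.int8)

    taper = np.clip((x0 - X) / 1.2, 0.0, 1.0)
    h = D / 2.0 + (1.7 - D / 2.0) * taper
    apex = np.where(X < 1.1, np.sqrt(np.clip(1 - ((1.1 - X) / 0.62) ** 2, 0, 1)), 1.0)
    h = h * apex
    in_lv_x = (X >= 0.5) & (X < x0)

    lv = in_lv_x & (np.abs(Y - cy) < h)
    septum = in_lv_x & (Y < cy - h) & (Y >= cy - h - 0.45)
    posterior = in_lv_x & (Y > cy + h) & (Y <= cy + h + 0.45)
    ao_x = (X >= x0) & (X <= 5.9)
    aorta = ao_x & (np.abs(Y - cy) < D / 2.0)
    ao_wall = ao_x & (np.abs(Y - cy) >= D / 2.0) & (np.abs(Y - cy) < D / 2.0 + 0.3)
    la = ((X - 4.6) / 0.95) ** 2 + ((Y - (cy + D / 2.0 + 1.05)) / 0.62) ** 2 <= 1.0
    la &= ~aorta & ~ao_wall
    rv = ((X - 1.6) / 0.95) ** 2 + ((Y - 0.55) / 0.38) ** 2 <= 1.0

    for mask, inten, code in (
        (septum, 0.80, 2), (posterior, 0.80, 3), (ao_wall, 0.85, 0),
        (rv, 0.06, 5), (lv, 0.05, 1), (aorta, 0.05, 6), (la, 0.06, 4),
    ):
        img[mask] = inten
        lab[mask] = code

    mv = _segment_mask(X, Y, (x0 - 0.05, cy + D / 2.0 - 0.05), (x0 - 0.9, cy + 0.75), 0.12)
    img[mv] = 0.65
    lab[mv] = 7

    leaf_int = _LEAFLET_CALCIFIED if spec.calcified else _LEAFLET_PLAIN
    hinge_top = (x0, cy - D / 2.0 + 0.06)
    hinge_bot = (x0, cy + D / 2.0 - 0.06)
    tip_x = x0 + 0.5 * D
    tip_top = (tip_x, cy - opening * (D / 2.0 - 0.10))
    tip_bot = (tip_x, cy + opening * (D / 2.0 - 0.10))
    av = _segment_mask(X, Y, hinge_top, tip_top, 0.12)
    av |= _segment_mask(X, Y, hinge_bot, tip_bot, 0.12)
    img[av] = leaf_int
    lab[av] = 8
    return img, lab


def _render_psax_frame(spec: PhantomSpec, X, Y, opening: float):
    """One PSAX-at-AV frame: aortic root ring with three leaflets."""
    cx = cyc = 3.2
    r0 = 0.62 * spec.true_lvot_diameter
    img = np.full(X.shape, 0.18, dtype=np.float32)
    lab = np.zeros(X.shape, dtype=np.int8)
    r = np.sqrt((X - cx) ** 2 + (Y - cyc) ** 2)
    img[(r >= r0) & (r < r0 + 0.3)] = 0.85
    lumen = r < r0
    img[lumen] = 0.05
    lab[lumen] = 6

    leaf_int = _LEAFLET_CALCIFIED if spec.calcified else _LEAFLET_PLAIN
    av = np.zeros(X.shape, dtype=bool)
    for ang in (90.0, 210.0, 330.0):
        a = math.radians(ang)
        hinge = (cx + r0 * math.cos(a), cyc + r0 * math.sin(a))
        inward = a + math.pi  # toward the centre
        swing = inward + math.radians(55.0) * opening
        tip = (hinge[0] + 0.92 * r0 * math.cos(swing),
               hinge[1] + 0.92 * r0 * math.sin(swing))
        av |= _segment_mask(X, Y, hinge, tip, 0.12)
    img[av] = leaf_int
    lab[av] = 8
    return img, lab


def _add_speckle(img: np.ndarray, noise_level: float, rng) -> np.ndarray:
    if noise_level == 0:
        return img
    g1 = ndimage.gaussian_filter(rng.standard_normal(img.shape), 0.8)
    g2 = rng.standard_normal(img.shape)
    out = img * (1.0 + 0.55 * noise_level * g1) + 0.10 * noise_level * g2
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _bbox(mask: np.ndarray, pad: int = 2):
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    return (max(int(rows.min()) - pad, 0), max(int(cols.min()) - pad, 0),
            min(int(rows.max()) + 1 + pad, h), min(int(cols.max()) + 1 + pad, w))


def render_views(spec: PhantomSpec, resolution: int = 128,
                 n_frames: int = 16) -> tuple[EchoVideo, EchoVideo, PhantomTruth]:
    """Render the PLAX and PSAX clips of a spec plus their ground truth.

    The clips cover exactly one cardiac cycle.  Rendering is a pure function
    of the spec (including its seed): identical inputs give identical pixels.
    """
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    X, Y, spacing = _grid(resolution)
    opening = _opening_curve(spec, n_frames)
    fps = n_frames / spec.cycle_duration

    rng_plax = np.random.default_rng([spec.seed, 11])
    rng_psax = np.random.default_rng([spec.seed, 13])

    plax_frames, plax_labels, psax_frames, psax_labels = [], [], [], []
    for o in opening:
        img, lab = _render_plax_frame(spec, X, Y, float(o))
        plax_frames.append(_add_speckle(img, spec.noise_level, rng_plax))
        plax_labels.append(lab)
        img, lab = _render_psax_frame(spec, X, Y, float(o))
        psax_frames.append(_add_speckle(img, spec.noise_level, rng_psax))
        psax_labels.append(lab)

    plax_lab = np.stack(plax_labels)
    psax_lab = np.stack(psax_labels)
    truth = PhantomTruth(
        measurements=analytic_truth(spec),
        label_map_truth=plax_lab,
        psax_label_map_truth=psax_lab,
        leaflet_box={"plax": _bbox(np.any(plax_lab == 8, axis=0)),
                     "psax": _bbox(np.any(psax_lab == 8, axis=0))},
        peak_frame=int(np.argmax(opening)),
        opening=opening,
    )
    plax = EchoVideo(np.stack(plax_frames), "plax", fps, spacing, spec.patient_id)
    psax = EchoVideo(np.stack(psax_frames), "psax", fps, spacing, spec.patient_id)
    return plax, psax, truth


def render_doppler(spec: PhantomSpec,
                   calibration: Optional[DopplerCalibration] = None,
                   view: str = "av_cw",
                   n_cycles: int = 3) -> tuple[DopplerSpectrum, VelocityTrace]:
    """Render a spectral-Doppler spectrogram and its truth velocity trace.

    ``view`` selects the transvalvular CW jet ("av_cw", peak = true Vmax) or
    the LVOT PW trace ("lvot_pw", peak solved from the LVOT VTI).  The
    envelope follows v(t) = Vpeak sin(pi t / T_ej) in each ejection window
    and is filled towards ``flow_side`` from the baseline.
    """
    cal = calibration or DopplerCalibration()
    if view == "av_cw":
        vpeak, modality = spec.true_vmax, "CW"
    elif view == "lvot_pw":
        vpeak = spec.true_lvot_vti / ((2.0 / math.pi) * spec.ejection_duration * 100.0)
        modality = "PW"
    else:
        raise ValueError(f"unknown doppler view {view!r}")
    if vpeak <= 0:
        raise ValueError("peak velocity must be positive (no ejection)")
    depth_rows = int(math.ceil(vpeak / cal.velocity_per_row))
    if cal.baseline_row + depth_rows >= cal.n_rows:
        raise ValueError("peak velocity exceeds the spectrogram velocity axis")

    cycle = spec.cycle_duration
    n_cols = int(round(n_cycles * cycle / cal.time_per_col))
    t = (np.arange(n_cols) + 0.5) * cal.time_per_col
    phase = ((t - 0.08 * cycle) % cycle) / spec.ejection_duration
    in_ej = (t % cycle >= 0.08 * cycle) & (phase <= 1.0)
    v = np.where(in_ej, vpeak * np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)

    img = np.full((cal.n_rows, n_cols), 0.03, dtype=np.float32)
    depth = np.rint(v / cal.velocity_per_row).astype(int)
    rows = np.arange(cal.n_rows)[:, None]
    offset = rows - cal.baseline_row if cal.flow_side == "below" else cal.baseline_row - rows
    img[(offset >= 1) & (offset <= depth[None, :])] = 0.80

    if spec.noise_level > 0:
        rng = np.random.default_rng([spec.seed, 17 if view == "av_cw" else 19])
        img = np.clip(img + 0.15 * spec.noise_level * rng.standard_normal(img.shape),
                      0.0, 1.0).astype(np.float32)

    spectrum = DopplerSpectrum(
        intensity=img, velocity_per_row=cal.velocity_per_row,
        time_per_col=cal.time_per_col, baseline_row=cal.baseline_row,
        flow_side=cal.flow_side, modality=modality, view_tag=view,
        patient_id=spec.patient_id)
    return spectrum, VelocityTrace(times=t, velocities=v)


def envelope_truth_mask(spectrum: DopplerSpectrum, trace: VelocityTrace) -> np.ndarray:
    """Binary truth mask of the filled envelope implied by a truth trace."""
    depth = np.rint(trace.velocities / spectrum.velocity_per_row).astype(int)
    rows = np.arange(spectrum.intensity.shape[0])[:, None]
    offset = (rows - spectrum.baseline_row if spectrum.flow_side == "below"
              else spectrum.baseline_row - rows)
    return (offset >= 1) & (offset <= depth[None, :])


def leaflet_opening_gap(label_map: np.ndarray, pixel_spacing: float = 1.0) -> float:
    """Leaflet orifice gap (cm) measured from one truth label map.

    The gap is the vertical clearance between the two (PLAX) or several
    (PSAX) leaflet components; a single coapted component has zero gap.
    """
    av = np.asarray(label_map) == 8
    if not av.any():
        return 0.0
    comp, n = ndimage.label(av)
    if n < 2:
        return 0.0
    rows = [np.nonzero(comp == i + 1)[0] for i in range(n)]
    order = np.argsort([r.mean() for r in rows])
    top, bottom = rows[order[0]], rows[order[-1]]
    return max(int(bottom.min()) - int(top.max()) - 1, 0) * pixel_spacing
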