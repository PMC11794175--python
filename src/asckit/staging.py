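"""Guideline staging of aortic stenosis from conventional measurements.

The engine implements the standard severity table:

==============  =====================  ==============  ==================
Stage           Vmax (m/s)             mPG (mmHg)      AVA (cm^2)
==============  =====================  ==============  ==================
Normal          < 2, no calcification  --              --
AV sclerosis    < 2, calcified         --              --
Mild            2-2.9                  < 20            > 1.5
Moderate        3-3.9                  20-39           1 < AVA <= 1.5
Severe          >= 4                   >= 40           <= 1
==============  =====================  ==============  ==================

Printed band gaps (2.9 -> 3, 39 -> 40) are closed as half-open intervals
[2, 3), [3, 4) and [20, 40) so every input falls in exactly one band; severe
bounds are inclusive as printed (>= 4 m/s, >= 40 mmHg, AVA <= 1).

A low mPG or a large AVA cannot separate normal/sclerosis from mild, so each
parameter maps to the *set* of stages it is compatible with and the engine
intersects the sets.  Disagreement is never resolved by force: the result is
an indeterminate stage with discordance flags, mirroring how discordant
cases are excluded from consistent labelling.
"""

from __future__ import annotations

import math
from typing import Optional

from .datatypes import ASMeasurements, ASStage, Stage, StageFlag

__all__ = [
    "stage_from_measurements",
    "detect_discordance",
    "compute_ava_continuity",
    "bernoulli_pressure",
    "vmax_band",
    "mpg_band",
    "ava_band",
]

_LOW = frozenset({Stage.NORMAL, Stage.SCLEROSIS, Stage.MILD})
_NORMAL_PAIR = frozenset({Stage.NORMAL, Stage.SCLEROSIS})


def vmax_band(vmax: float) -> frozenset:
    """Stages compatible with a peak aortic-jet velocity (m/s)."""
    if vmax < 0:
        raise ValueError("vmax must be >= 0")
    if vmax < 2.0:
        return _NORMAL_PAIR
    if vmax < 3.0:
        return frozenset({Stage.MILD})
    if vmax < 4.0:
        return frozenset({Stage.MODERATE})
    return frozenset({Stage.SEVERE})


def mpg_band(mpg: float) -> frozenset:
    """Stages compatible with a mean pressure gradient (mmHg)."""
    if mpg < 0:
        raise ValueError("mpg must be >= 0")
    if mpg < 20.0:
        return _LOW
    if mpg < 40.0:
        return frozenset({Stage.MODERATE})
    return frozenset({Stage.SEVERE})


def ava_band(ava: float) -> frozenset:
    """Stages compatible with an aortic valve area (cm^2)."""
    if ava <= 0:
        raise ValueError("ava must be > 0")
    if ava > 1.5:
        return _LOW
    if ava > 1.0:
        return frozenset({Stage.MODERATE})
    return frozenset({Stage.SEVERE})


def _severity_label(band: frozenset) -> Optional[Stage]:
    """Scalar severity label of a band for discordance bookkeeping.

    The sub-mild bands (normal pair, low mPG/AVA) all label as MILD-or-less
    and are represented by Stage.MILD here only for pair comparisons.
    """
    if band == frozenset({Stage.SEVERE}):
        return Stage.SEVERE
    if band == frozenset({Stage.MODERATE}):
        return Stage.MODERATE
    return Stage.MILD


def detect_discordance(m: ASMeasurements) -> frozenset:
    """Flags describing how available parameters disagree.

    Requires at least two available parameters; with fewer there is nothing
    to compare and the empty set is returned.
    """
    avail = [k for k in ("vmax", "mpg", "ava") if getattr(m, k) is not None]
    if len(avail) < 2:
        return frozenset()
    flags = set()
    if m.vmax is not None and m.mpg is not None:
        pair = {_severity_label(vmax_band(m.vmax)), _severity_label(mpg_band(m.mpg))}
        if pair == {Stage.MILD, Stage.MODERATE}:
            flags.add(StageFlag.MILD_TO_MODERATE)
        elif pair == {Stage.MODERATE, Stage.SEVERE}:
            flags.add(StageFlag.MODERATE_TO_SEVERE)
    if m.ava is not None and m.ava < 1.0:
        vmax_severe = m.vmax is not None and vmax_band(m.vmax) == {Stage.SEVERE}
        mpg_severe = m.mpg is not None and mpg_band(m.mpg) == {Stage.SEVERE}
        if not vmax_severe and not mpg_severe:
            flags.add(StageFlag.LFLG_SEVERE_PATTERN)
    return frozenset(flags)


def stage_from_measurements(m: ASMeasurements) -> ASStage:
    """Stage a measurement record against the severity table.

    Each available parameter contributes the set of stages it is compatible
    with; the intersection decides the outcome:

    * a single stage -> that stage, concordant;
    * the normal/sclerosis pair -> split by the calcification flag (flagged
      insufficient when calcification is unknown, reported as normal-band);
    * mPG and AVA both low with no Vmax -> mild (the printed mild row);
    * empty intersection -> indeterminate with discordance flags;
    * nothing available -> indeterminate with an insufficient-data flag.
    """
    bands = []
    if m.vmax is not None:
        bands.append(vmax_band(m.vmax))
    if m.mpg is not None:
        bands.append(mpg_band(m.mpg))
    if m.ava is not None:
        bands.append(ava_band(m.ava))
    if not bands:
        return ASStage(stage=None, concordant=False,
                       flags={StageFlag.INSUFFICIENT_DATA})

    inter = frozenset.intersection(*bands)
    if not inter:
        return ASStage(stage=None, concordant=False, flags=detect_discordance(m))

    if len(inter) == 1:
        return ASStage(stage=next(iter(inter)), concordant=True)

    if inter == _NORMAL_PAIR:
        if m.calcified is None:
            return ASStage(stage=Stage.NORMAL, concordant=False,
                           flags={StageFlag.INSUFFICIENT_DATA})
        return ASStage(stage=Stage.SCLEROSIS if m.calcified else Stage.NORMAL,
                       concordant=True)

    # inter is the sub-mild set {normal, sclerosis, mild}: no Vmax available.
    if m.mpg is not None and m.ava is not None:
        # mPG < 20 with AVA > 1.5 is the printed definition of mild AS.
        return ASStage(stage=Stage.MILD, concordant=True)
    # A single low parameter cannot exclude a normal valve.
    return ASStage(stage=Stage.MILD, concordant=False,
                   flags={StageFlag.INSUFFICIENT_DATA})


def compute_ava_continuity(d_lvot: float, vti_lvot: float, vti_av: float) -> float:
    """Continuity-equation valve area: AVA = pi (D/2)^2 * VTI_LVOT / VTI_AV.

    Parameters are the LVOT diameter (cm) and the LVOT and transvalvular
    velocity-time integrals (cm); the result is in cm^2.
    """
    for name, v in (("d_lvot", d_lvot), ("vti_lvot", vti_lvot), ("vti_av", vti_av)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    return math.pi * (d_lvot / 2.0) ** 2 * vti_lvot / vti_av


def bernoulli_pressure(v: float) -> float:
    """Simplified-Bernoulli instantaneous gradient: delta-P = 4 v^2 (mmHg)."""
    if v < 0:
        raise ValueError("velocity must be >= 0")
    return 4.0 * v * v
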