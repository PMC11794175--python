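"""Staging engine: severity-table rules, discordance, continuity equation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asckit.datatypes import ASMeasurements, Stage, StageFlag
from asckit.staging import (ava_band, bernoulli_pressure, compute_ava_continuity,
                            detect_discordance, mpg_band, stage_from_measurements,
                            vmax_band)


# --------------------------------------------------------------------------
# independent brute-force oracle: a literal transcription of the severity
# table (kept deliberately separate from the set-intersection engine)
# --------------------------------------------------------------------------

def _oracle(vmax, mpg, ava, calcified):
    """Return (stage or None, concordant) by explicit per-row matching."""
    def vmax_cat(v):
        return 0 if v < 2 else 2 if v < 3 else 3 if v < 4 else 4

    def mpg_cat(g):
        return "low" if g < 20 else 3 if g < 40 else 4

    def ava_cat(a):
        return "low" if a > 1.5 else 3 if a > 1.0 else 4

    cats = []
    if vmax is not None:
        cats.append(vmax_cat(vmax))
    if mpg is not None:
        cats.append(mpg_cat(mpg))
    if ava is not None:
        cats.append(ava_cat(ava))
    if not cats:
        return None, False
    definite = {c for c in cats if c != "low"}
    if len(definite) > 1:
        return None, False               # two parameters in different bands
    # a "low" mPG (< 20) or large AVA (> 1.5) is only compatible with the
    # mild-or-less rows; against a moderate/severe parameter it is discordant
    if "low" in cats and (definite == {3} or definite == {4}):
        return None, False
    if definite == {0}:
        # normal band: a "low" mPG/AVA is compatible
        if calcified is None:
            return Stage.NORMAL, False
        return (Stage.SCLEROSIS if calcified else Stage.NORMAL), True
    if definite == {2}:
        return Stage.MILD, True
    if definite == {3}:
        return Stage.MODERATE, True
    if definite == {4}:
        return Stage.SEVERE, True
    # only "low" parameters: mild row needs both mPG < 20 and AVA > 1.5
    if vmax is None and mpg is not None and ava is not None:
        return Stage.MILD, True
    return Stage.MILD, False


@pytest.mark.parametrize("m, stage, concordant", [
    (dict(vmax=4.5, mpg=50, ava=0.8, calcified=True), Stage.SEVERE, True),
    (dict(vmax=1.2, calcified=False), Stage.NORMAL, True),
    (dict(vmax=1.8, calcified=True), Stage.SCLEROSIS, True),
    (dict(vmax=2.5, mpg=15, ava=1.8), Stage.MILD, True),
    (dict(vmax=3.5, mpg=25, ava=1.2), Stage.MODERATE, True),
    (dict(vmax=2.5), Stage.MILD, True),
    (dict(ava=0.9), Stage.SEVERE, True),
    (dict(mpg=45.0), Stage.SEVERE, True),
])
def test_table_rows(m, stage, concordant):
    result = stage_from_measurements(ASMeasurements(**m))
    assert result.stage == stage
    assert result.concordant == concordant


def test_no_parameters_is_indeterminate():
    result = stage_from_measurements(ASMeasurements(calcified=True))
    assert result.stage is None
    assert StageFlag.INSUFFICIENT_DATA in result.flags


def test_low_vmax_without_calcification_flagged():
    result = stage_from_measurements(ASMeasurements(vmax=1.5))
    assert result.stage == Stage.NORMAL
    assert not result.concordant
    assert StageFlag.INSUFFICIENT_DATA in result.flags


@pytest.mark.parametrize("m, expected", [
    (dict(vmax=2.8, mpg=25), {StageFlag.MILD_TO_MODERATE}),
    (dict(vmax=3.5, mpg=45), {StageFlag.MODERATE_TO_SEVERE}),
    (dict(vmax=3.5, mpg=30, ava=0.9), {StageFlag.LFLG_SEVERE_PATTERN}),
    (dict(vmax=4.2, mpg=45, ava=0.9), set()),
    (dict(vmax=2.8), set()),                       # one parameter: nothing to compare
])
def test_discordance_flags(m, expected):
    assert detect_discordance(ASMeasurements(**m)) == frozenset(expected)


def test_discordant_cases_get_no_forced_stage():
    result = stage_from_measurements(ASMeasurements(vmax=2.8, mpg=25))
    assert result.stage is None
    assert not result.concordant
    assert StageFlag.MILD_TO_MODERATE in result.flags


def test_band_partition_no_gaps_or_overlaps():
    for v in np.arange(0.0, 8.0, 0.001):
        assert len(vmax_band(float(v))) >= 1
    for g in np.arange(0.0, 80.0, 0.001):
        assert len(mpg_band(float(g))) >= 1
    for a in np.arange(0.001, 4.0, 0.001):
        assert len(ava_band(float(a))) >= 1
    # half-open boundaries behave as documented
    assert vmax_band(2.95) == {Stage.MILD}
    assert vmax_band(3.0) == {Stage.MODERATE}
    assert vmax_band(4.0) == {Stage.SEVERE}
    assert mpg_band(39.999) == {Stage.MODERATE}
    assert mpg_band(40.0) == {Stage.SEVERE}
    assert ava_band(1.0) == {Stage.SEVERE}
    assert ava_band(1.5) == {Stage.MODERATE}


def test_truth_table_equivalence_random_tuples():
    """10,000 random measurement tuples match the brute-force oracle."""
    rng = np.random.default_rng(42)
    for _ in range(10_000):
        vmax = float(rng.uniform(0.5, 6.0)) if rng.random() < 0.8 else None
        mpg = float(rng.uniform(1.0, 80.0)) if rng.random() < 0.8 else None
        ava = float(rng.uniform(0.3, 4.0)) if rng.random() < 0.8 else None
        calcified = bool(rng.random() < 0.5)
        if vmax is None and mpg is None and ava is None:
            continue
        m = ASMeasurements(vmax=vmax, mpg=mpg, ava=ava, calcified=calcified)
        result = stage_from_measurements(m)
        exp_stage, exp_conc = _oracle(vmax, mpg, ava, calcified)
        assert result.stage == exp_stage, m
        assert result.concordant == exp_conc, m


@given(vmax=st.floats(0.5, 6.0), mpg=st.floats(1.0, 80.0),
       ava=st.floats(0.3, 4.0), bump=st.floats(0.01, 1.5))
@settings(max_examples=200, deadline=None)
def test_monotone_in_severity(vmax, mpg, ava, bump):
    """Worsening one parameter never lowers a concordant stage."""
    base = stage_from_measurements(ASMeasurements(vmax=vmax, mpg=mpg, ava=ava,
                                                  calcified=True))
    if not base.concordant:
        return
    worse = stage_from_measurements(ASMeasurements(vmax=vmax + bump, mpg=mpg,
                                                   ava=ava, calcified=True))
    if worse.concordant:
        assert worse.stage >= base.stage


@pytest.mark.parametrize("d, vl, va, expected", [
    (2.0, 20.0, 80.0, 0.7854),
    (2.2, 22.0, 110.0, 0.7603),
])
def test_continuity_equation(d, vl, va, expected):
    assert compute_ava_continuity(d, vl, va) == pytest.approx(expected, abs=5e-5)


def test_continuity_identity_and_errors():
    d = 2.4
    assert compute_ava_continuity(d, 17.0, 17.0) == pytest.approx(
        math.pi * (d / 2) ** 2, rel=1e-12)
    with pytest.raises(ValueError):
        compute_ava_continuity(0.0, 20.0, 80.0)
    with pytest.raises(ValueError):
        compute_ava_continuity(2.0, 20.0, -1.0)


@pytest.mark.parametrize("v, expected", [(4.0, 64.0), (0.0, 0.0), (5.0, 100.0)])
def test_bernoulli_pressure(v, expected):
    assert bernoulli_pressure(v) == expected


def test_bernoulli_pressure_rejects_negative():
    with pytest.raises(ValueError):
        bernoulli_pressure(-0.1)
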