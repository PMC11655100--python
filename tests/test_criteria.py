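import math

import numpy as np
import pytest

from ecglvh.criteria import (
    CRITERIA_NAMES,
    THRESHOLDS,
    TOP_FIVE,
    combine_any,
    evaluate_criteria,
    to_millimeters,
)
from ecglvh.records import STANDARD_LEADS, ConfigurationError

EPS = 0.11  # mm, just over one hundredth of a mV


def _morph(mm: dict[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    """Per-lead features from (wave, lead) -> amplitude in mm (signed)."""
    out = {lead: {f"{w}_amp": 0.0 for w in ("P", "Q", "R", "S", "J", "T")}
           for lead in STANDARD_LEADS}
    for (wave, lead), v in mm.items():
        out[lead][f"{wave}_amp"] = v / 10.0  # back to mV
    return out


def _report(mm, qrs_ms=100.0):
    return evaluate_criteria(_morph(mm), qrs_ms)


def test_millimeter_conversion():
    assert to_millimeters(1.0) == 10.0
    assert abs(to_millimeters(-2.3)) == pytest.approx(23.0)
    assert to_millimeters(0.0) == 0.0


def test_count_and_all_negative_on_zero_input():
    rep = _report({})
    assert len(rep.results) == 22
    assert set(rep.results) == set(CRITERIA_NAMES)
    # Holt is a ratio, undefined at zero denominator; all others negative
    for name, r in rep.results.items():
        if name == "Holt":
            assert r.positive is None
        else:
            assert r.positive is False


# one boundary case per criterion: operands putting the LHS exactly at the
# threshold (negative, strict inequality) and just above it (positive)
BOUNDARY_CASES = {
    "Lewis": lambda thr, eps: {("R", "I"): thr + eps, ("S", "III"): 0.0},
    "Gubner1": lambda thr, eps: {("R", "I"): thr + eps, ("S", "III"): 0.0},
    "Gubner2": lambda thr, eps: {("R", "I"): thr + eps},
    "Sokolow-Lyon1": lambda thr, eps: {("R", "aVL"): thr + eps},
    "Goldberger": lambda thr, eps: {("R", "aVF"): thr + eps},
    "Schack": lambda thr, eps: {("Q", "aVR"): thr + eps, ("S", "aVR"): 1.0},
    "Romhilt1": lambda thr, eps: {("R", "II"): thr / 2 + eps, ("S", "II"): thr / 2},
    "Wilson1": lambda thr, eps: {("S", "V1"): -(thr + eps)},
    "Mazzoleni": lambda thr, eps: {("S", "V2"): -(thr + eps)},
    "Sokolow-Lyon2": lambda thr, eps: {("S", "V1"): -20.0,
                                       ("R", "V5"): thr - 20.0 + eps},
    "Romhilt2": lambda thr, eps: {("S", "V2"): -25.0, ("R", "V6"): thr - 25.0 + eps},
    "Murphy": lambda thr, eps: {("S", "V2"): -20.0, ("R", "V5"): thr - 20.0 + eps},
    "Grant1": lambda thr, eps: {("S", "V1"): -22.0, ("R", "V6"): thr - 22.0 + eps},
    "Grant2": lambda thr, eps: {("R", "V4"): thr - 10.0 + eps, ("S", "V4"): -10.0},
    "Holt": lambda thr, eps: {("R", "V5"): 10.0 * (thr + eps), ("R", "V6"): 10.0},
    "McPhie": lambda thr, eps: {("R", "V4"): thr + eps},
    "Wolff": lambda thr, eps: {("S", "V2"): -30.0, ("R", "V4"): thr - 30.0 + eps},
    "Wilson2": lambda thr, eps: {("R", "V5"): thr + eps},
    "Wilson3": lambda thr, eps: {("R", "V6"): thr + eps},
    "Siegel": lambda thr, eps: {**{("R", ld): 14.0 for ld in STANDARD_LEADS},
                                ("R", "I"): thr - 14.0 * 11 + eps},
    "Molloy1": lambda thr, eps: {("R", "aVL"): (thr / 100.0) + eps,
                                 ("S", "V3"): 0.0},
    "Molloy2": lambda thr, eps: {("R", "I"): (thr / 100.0) + eps},
}


@pytest.mark.parametrize("name", CRITERIA_NAMES)
def test_boundary_behaviour(name):
    """Just above threshold is positive; exactly at threshold is negative."""
    thr = THRESHOLDS[name]
    above = _report(BOUNDARY_CASES[name](thr, EPS), qrs_ms=100.0)
    assert above.results[name].positive is True, name
    at = _report(BOUNDARY_CASES[name](thr, 0.0), qrs_ms=100.0)
    assert at.results[name].lhs_value == pytest.approx(thr, abs=1e-9)
    assert at.results[name].positive is False, name


def test_sokolow_lyon2_worked_example():
    rep = _report({("S", "V1"): -20.0, ("R", "V5"): 16.0})
    r = rep.results["Sokolow-Lyon2"]
    assert r.lhs_value == pytest.approx(36.0)
    assert r.positive is True


def test_holt_ratio_worked_example():
    rep = _report({("R", "V5"): 10.0, ("R", "V6"): 8.0})
    r = rep.results["Holt"]
    assert r.lhs_value == pytest.approx(1.25)
    assert r.positive is True


def test_depth_magnitudes_used_for_s_waves():
    """A deeply negative S contributes its magnitude."""
    rep = _report({("S", "V1"): -24.0})
    assert rep.results["Wilson1"].positive is True


# Lewis and Gubner1 subtract printed magnitudes, so they are monotone only
# in their added terms; all other criteria are monotone in every operand
_MONOTONE = tuple(n for n in CRITERIA_NAMES
                  if n not in ("Lewis", "Gubner1", "Holt"))


@pytest.mark.parametrize("name", _MONOTONE)
def test_monotone_in_each_operand(name):
    """Raising any wave magnitude never flips a positive to negative."""
    base_mm = BOUNDARY_CASES[name](THRESHOLDS[name], EPS)
    rep0 = _report(base_mm, qrs_ms=100.0)
    assert rep0.results[name].positive is True
    for key in base_mm:
        bigger = dict(base_mm)
        bigger[key] = bigger[key] * 1.5 if bigger[key] != 0 else 5.0
        rep = _report(bigger, qrs_ms=100.0)
        assert rep.results[name].positive is True


@pytest.mark.parametrize("name", ["Lewis", "Gubner1"])
def test_subtractive_criteria_monotone_in_added_term(name):
    base_mm = BOUNDARY_CASES[name](THRESHOLDS[name], EPS)
    bigger = dict(base_mm)
    bigger[("R", "I")] = bigger[("R", "I")] + 5.0
    assert _report(bigger).results[name].positive is True


def test_holt_monotone_in_numerator_only():
    base = {("R", "V5"): 10.0 + EPS, ("R", "V6"): 10.0}
    assert _report(base).results["Holt"].positive is True
    taller_v5 = {**base, ("R", "V5"): 20.0}
    assert _report(taller_v5).results["Holt"].positive is True


def test_missing_operand_propagates_to_missing_result():
    morph = _morph({("S", "V1"): -20.0, ("R", "V5"): 16.0})
    del morph["V1"]["S_amp"]
    rep = evaluate_criteria(morph, 100.0)
    assert rep.results["Sokolow-Lyon2"].positive is None
    assert math.isnan(rep.results["Sokolow-Lyon2"].lhs_value)
    # unrelated criteria unaffected
    assert rep.results["Gubner2"].positive is False


def test_combine_any_rules():
    rep = _report({("R", ld): 16.0 for ld in STANDARD_LEADS})  # Siegel positive
    assert rep.results["Siegel"].positive is True
    assert combine_any(rep, list(TOP_FIVE)) is True
    neg = _report({})
    assert combine_any(neg, list(TOP_FIVE)) is False
    assert combine_any(neg, []) is False
    with pytest.raises(ConfigurationError):
        combine_any(neg, ["NotACriterion"])


def test_combination_monotone_under_set_inclusion():
    rep = _report({("R", "aVL"): 12.0})  # Sokolow-Lyon1 positive
    small = combine_any(rep, ["Siegel"])
    larger = combine_any(rep, ["Siegel", "Sokolow-Lyon1"])
    assert (not small) and larger


def test_missing_member_counts_as_negative_in_combination():
    morph = _morph({})
    for lead in STANDARD_LEADS:
        morph[lead]["R_amp"] = math.nan
    rep = evaluate_criteria(morph, 100.0)
    assert rep.results["McPhie"].positive is None
    assert combine_any(rep, ["McPhie"]) is False
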