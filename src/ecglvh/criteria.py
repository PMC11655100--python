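"""Codified clinical LVH voltage criteria and their "any-of" combinations.

Twenty-two published threshold rules on ECG wave amplitudes are evaluated on
the extracted per-lead median amplitudes. Amplitudes enter the formulas as
magnitudes in millimetres at the standard calibration of 10 mm/mV (so an S
"depth" is |S|), and each rule is a strict inequality evaluated exactly as
codified — e.g. Sokolow-Lyon: |S(V1)| + |R(V5)| > 35 mm. "Any lead" clauses
take the maximum over the named options; "total 12-lead voltage" is the sum
of |R| + |S| over all leads; the two Molloy voltage-duration products
multiply by the QRS duration in ms.

A missing operand makes the criterion result missing (never negative);
combinations treat missing member results as negative votes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .records import LIMB_LEADS, PRECORDIAL_LEADS, STANDARD_LEADS, ConfigurationError

#: clinical calibration: 10 mm per mV
MM_PER_MV = 10.0

#: the five criteria with the best discriminative performance, combined
#: "any-of" for the clinical comparison
TOP_FIVE: tuple[str, ...] = ("Siegel", "McPhie", "Sokolow-Lyon1", "Grant2", "Romhilt1")


def to_millimeters(amp_mv: float) -> float:
    """Convert an amplitude in mV to mm at 10 mm/mV (sign preserved)."""
    return MM_PER_MV * amp_mv


@dataclass
class CriterionResult:
    lhs_value: float
    threshold: float
    positive: Optional[bool]  #: None when an operand is missing


@dataclass
class CriteriaReport:
    """Results of the 22 criteria plus named combinations."""

    results: dict[str, CriterionResult] = field(default_factory=dict)
    combinations: dict[str, bool] = field(default_factory=dict)

    def positives(self) -> dict[str, Optional[bool]]:
        return {name: r.positive for name, r in self.results.items()}

    def to_series(self) -> pd.Series:
        """0/1/NaN per criterion, for CSV export."""
        out = {}
        for name, r in self.results.items():
            out[name] = np.nan if r.positive is None else float(r.positive)
        for name, v in self.combinations.items():
            out[name] = float(v)
        return pd.Series(out)


class _Amps:
    """Magnitude (mm) lookup over the per-lead morphological features."""

    def __init__(self, morph: dict[str, dict[str, float]]):
        self._morph = morph

    def __call__(self, wave: str, lead: str) -> float:
        feats = self._morph.get(lead, {})
        val = feats.get(f"{wave}_amp", math.nan)
        return abs(to_millimeters(val)) if np.isfinite(val) else math.nan

    def max(self, pairs: list[tuple[str, str]]) -> float:
        vals = [self(w, ld) for w, ld in pairs]
        return max(vals) if all(np.isfinite(v) for v in vals) else math.nan

    def total_voltage(self) -> float:
        tot = 0.0
        for lead in STANDARD_LEADS:
            r, s = self("R", lead), self("S", lead)
            if not (np.isfinite(r) and np.isfinite(s)):
                return math.nan
            tot += r + s
        return tot


def _ratio(num: float, den: float) -> float:
    if not (np.isfinite(num) and np.isfinite(den)) or den < 0.1:
        return math.nan
    return num / den


def _strict_max(values) -> float:
    """Maximum with NaN propagation (any missing operand -> missing)."""
    vals = list(values)
    return max(vals) if all(np.isfinite(v) for v in vals) else math.nan


# (name, threshold, lhs(amps, qrs_ms)); thresholds in mm, except the two
# voltage-duration products in mm*ms and the dimensionless Holt ratio
_CRITERIA: list[tuple[str, float, Callable[[_Amps, float], float]]] = [
    ("Lewis", 16.0,
     lambda a, q: (a("R", "I") - a("S", "I")) + (a("S", "III") - a("R", "III"))),
    ("Gubner1", 25.0, lambda a, q: a("R", "I") - a("S", "III")),
    ("Gubner2", 15.0, lambda a, q: a("R", "I")),
    ("Sokolow-Lyon1", 11.0, lambda a, q: a("R", "aVL")),
    ("Goldberger", 20.0, lambda a, q: a("R", "aVF")),
    ("Schack", 19.0, lambda a, q: a.max([("Q", "aVR"), ("S", "aVR")])),
    ("Romhilt1", 19.0,
     lambda a, q: _strict_max(a("R", ld) + a("S", ld) for ld in LIMB_LEADS)),
    ("Wilson1", 23.0, lambda a, q: a("S", "V1")),
    ("Mazzoleni", 25.0, lambda a, q: a("S", "V2")),
    ("Sokolow-Lyon2", 35.0, lambda a, q: a("S", "V1") + a("R", "V5")),
    ("Romhilt2", 45.0,
     lambda a, q: a("S", "V2") + a.max([("R", "V5"), ("R", "V6")])),
    ("Murphy", 35.0,
     lambda a, q: a.max([("S", "V1"), ("S", "V2")])
     + a.max([("R", "V5"), ("R", "V6")])),
    ("Grant1", 40.0,
     lambda a, q: a.max([("S", "V1"), ("S", "V2")]) + a("R", "V6")),
    ("Grant2", 35.0,
     lambda a, q: _strict_max(a("R", ld) + a("S", ld) for ld in PRECORDIAL_LEADS)),
    ("Holt", 1.0, lambda a, q: _ratio(a("R", "V5"), a("R", "V6"))),
    ("McPhie", 26.0, lambda a, q: _strict_max(a("R", ld) for ld in PRECORDIAL_LEADS)),
    ("Wolff", 45.0,
     lambda a, q: a("S", "V2") + a.max([("R", "V4"), ("R", "V5")])),
    ("Wilson2", 33.0, lambda a, q: a("R", "V5")),
    ("Wilson3", 25.0, lambda a, q: a("R", "V6")),
    ("Siegel", 175.0, lambda a, q: a.total_voltage()),
    ("Molloy1", 2436.0,
     lambda a, q: (a("R", "aVL") + a("S", "V3")) * q),
    ("Molloy2", 2436.0, lambda a, q: a.total_voltage() * q),
]

CRITERIA_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _CRITERIA)
THRESHOLDS: dict[str, float] = {name: thr for name, thr, _ in _CRITERIA}


def evaluate_criteria(
    morph: dict[str, dict[str, float]], qrs_duration_ms: float
) -> CriteriaReport:
    """Evaluate all 22 criteria from per-lead morphological features.

    ``qrs_duration_ms`` enters only the two voltage-duration products. Each
    criterion is positive iff its left-hand value strictly exceeds the
    threshold; a non-finite left-hand value makes the result missing.
    The report also carries the "any-of" result of the top-five combination
    under the key ``combo_top5``.
    """
    amps = _Amps(morph)
    report = CriteriaReport()
    for name, threshold, lhs_fn in _CRITERIA:
        try:
            lhs = float(lhs_fn(amps, qrs_duration_ms))
        except (TypeError, ValueError):
            lhs = math.nan
        positive = None if not np.isfinite(lhs) else bool(lhs > threshold)
        report.results[name] = CriterionResult(lhs, threshold, positive)
    report.combinations["combo_top5"] = combine_any(report, list(TOP_FIVE))
    return report


def evaluate_feature_row(row: pd.Series,
                         qrs_duration_ms: Optional[float] = None) -> CriteriaReport:
    """Evaluate the criteria battery from one assembled feature row.

    Amplitudes are read from the ``<wave>_amp_<lead>`` columns; the QRS
    duration defaults to the median of the per-lead ``QRS_dur_<lead>``
    columns.
    """
    morph = {
        lead: {
            f"{wave}_amp": float(row.get(f"{wave}_amp_{lead}", math.nan))
            for wave in ("P", "Q", "R", "S", "J", "T")
        }
        for lead in STANDARD_LEADS
    }
    if qrs_duration_ms is None:
        durs = [row.get(f"QRS_dur_{lead}", math.nan) for lead in STANDARD_LEADS]
        durs = [d for d in durs if np.isfinite(d)]
        qrs_duration_ms = float(np.median(durs)) if durs else math.nan
    return evaluate_criteria(morph, qrs_duration_ms)


def combine_any(report: CriteriaReport, names: list[str]) -> bool:
    """True iff at least one named criterion is positive (missing = negative)."""
    unknown = [n for n in names if n not in report.results]
    if unknown:
        raise ConfigurationError(f"unknown criteria: {unknown}")
    return any(report.results[n].positive is True for n in names)
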