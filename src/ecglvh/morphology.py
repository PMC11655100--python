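"""Per-lead morphological ECG features and per-record feature assembly.

Nineteen features are measured on every lead from the delineated beats:

* signed amplitudes of P, Q, R, S, J and T relative to the beat baseline
  (mV, median across beats),
* amplitude ratios R/P and R/T of the median amplitudes,
* intervals PR, PS, PT, QT, QRS, RS, ToT and TTe (ms, median across beats),
* ascending and descending T-wave slopes (mV/s, two-point secants), and
* the percentage of QRS samples below baseline.

Interval endpoints: PR = P_on→QRS_on, PS = P_on→S, PT = P_on→T_off,
QT = QRS_on→T_off, QRS = QRS_on→J, RS = R→S, ToT = T_on→T_peak,
TTe = T_peak→T_off. A missing landmark yields a missing feature, never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import STANDARD_LEADS, ConfigurationError, EcgRecord, FiducialMap

#: the 19 per-lead morphological feature names, in canonical order
MORPH_FEATURES: tuple[str, ...] = (
    "P_amp", "Q_amp", "R_amp", "S_amp", "J_amp", "T_amp",
    "R_over_P", "R_over_T",
    "PR_int", "PS_int", "PT_int", "QT_int", "QRS_dur", "RS_int",
    "ToT_int", "TTe_int",
    "T_slope_asc", "T_slope_des", "QRS_neg_pct",
)

_AMP_LANDMARKS = {
    "P_amp": "P_peak", "Q_amp": "Q", "R_amp": "R",
    "S_amp": "S", "J_amp": "J", "T_amp": "T_peak",
}
_INTERVALS = {
    "PR_int": ("P_on", "QRS_on"),
    "PS_int": ("P_on", "S"),
    "PT_int": ("P_on", "T_off"),
    "QT_int": ("QRS_on", "T_off"),
    "QRS_dur": ("QRS_on", "J"),
    "RS_int": ("R", "S"),
    "ToT_int": ("T_on", "T_peak"),
    "TTe_int": ("T_peak", "T_off"),
}

#: |denominator| below this (mV) makes an amplitude ratio missing
RATIO_MIN_DENOM_MV = 0.01


def _median(values: list[float]) -> float:
    return float(np.median(values)) if values else np.nan


def extract_lead_features(
    record: EcgRecord, fiducials: FiducialMap, lead: str
) -> dict[str, float]:
    """Compute the 19 morphological features for one lead.

    Per-beat measurements are aggregated by the median; a lead without any
    delineated beat returns all-missing features.
    """
    if lead not in STANDARD_LEADS:
        raise ConfigurationError(f"unknown lead {lead!r}")
    x = record.lead(lead)
    fs = record.fs
    beats = fiducials.beats.get(lead, [])
    feats: dict[str, float] = {name: np.nan for name in MORPH_FEATURES}
    if not beats:
        return feats

    for name, lm in _AMP_LANDMARKS.items():
        vals = [x[b.get(lm)] - b.baseline_mv for b in beats if b.get(lm) is not None]
        feats[name] = _median(vals)

    for name, (a, z) in _INTERVALS.items():
        vals = [
            (b.get(z) - b.get(a)) * 1000.0 / fs
            for b in beats
            if b.get(a) is not None and b.get(z) is not None
        ]
        feats[name] = _median(vals)

    for ratio, denom_name in (("R_over_P", "P_amp"), ("R_over_T", "T_amp")):
        denom = feats[denom_name]
        if np.isfinite(denom) and abs(denom) >= RATIO_MIN_DENOM_MV:
            feats[ratio] = feats["R_amp"] / denom

    asc, des = [], []
    for b in beats:
        if b.T_on is not None and b.T_peak is not None and b.T_peak > b.T_on:
            asc.append((x[b.T_peak] - x[b.T_on]) * fs / (b.T_peak - b.T_on))
        if b.T_off is not None and b.T_peak is not None and b.T_off > b.T_peak:
            des.append((x[b.T_off] - x[b.T_peak]) * fs / (b.T_off - b.T_peak))
    feats["T_slope_asc"] = _median(asc)
    feats["T_slope_des"] = _median(des)

    neg = []
    for b in beats:
        if b.QRS_on is not None and b.J is not None and b.J > b.QRS_on:
            seg = x[b.QRS_on:b.J] - b.baseline_mv
            neg.append(100.0 * float(np.mean(seg < 0)))
    feats["QRS_neg_pct"] = _median(neg)
    return feats


def extract_morphology(
    record: EcgRecord, fiducials: FiducialMap
) -> dict[str, dict[str, float]]:
    """All 12 leads' morphological features (228 values)."""
    return {lead: extract_lead_features(record, fiducials, lead)
            for lead in STANDARD_LEADS}


def assemble_feature_vector(
    morph: dict[str, dict[str, float]],
    hermite: dict[str, "HermiteFit"],  # noqa: F821 - see ecglvh.hermite
    v_index: float,
) -> pd.Series:
    """Assemble one record's named feature row.

    19×12 morphological + (4 coefficients + RMSE)×12 Hermite + 1 V-index
    = 289 named values. Column names follow ``<feature>_<lead>``.
    """
    row: dict[str, float] = {}

    def put(name: str, value: float) -> None:
        if name in row:
            raise ConfigurationError(f"feature name collision: {name}")
        row[name] = value

    for lead in STANDARD_LEADS:
        lead_feats = morph.get(lead) or {f: np.nan for f in MORPH_FEATURES}
        for feat in MORPH_FEATURES:
            put(f"{feat}_{lead}", lead_feats.get(feat, np.nan))
    for lead in STANDARD_LEADS:
        fit = hermite.get(lead)
        for i in range(4):
            put(f"herm_c{i + 1}_{lead}",
                np.nan if fit is None else float(fit.coeffs[i]))
        put(f"herm_rmse_{lead}", np.nan if fit is None else float(fit.rmse))
    put("v_index", v_index)
    return pd.Series(row, dtype=float)
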