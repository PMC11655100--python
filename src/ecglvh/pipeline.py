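"""End-to-end feature extraction: records in, 289-column feature matrix out.

For each record: R peaks are detected on lead II, all leads are delineated,
averaged-beat templates are built under quality control, and the three
feature families are computed — 19 morphological features per lead, the
4-coefficient + RMSE Hermite description of each lead's averaged QRS, and
the single V-index. Records failing template quality control are excluded
with a reason code rather than contributing unreliable features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .delineation import (
    Exclusion,
    build_templates,
    delineate_waves,
    detect_r_peaks,
)
from .hermite import fit_template_qrs
from .io import FeatureMatrix
from .morphology import assemble_feature_vector, extract_morphology
from .records import EcgRecord, FiducialMap, NoBeatsError, STANDARD_LEADS
from .vindex import compute_v_index, ensemble_from_templates

logger = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    features: FeatureMatrix
    exclusions: list[Exclusion] = field(default_factory=list)


def extract_record_features(
    record: EcgRecord,
    fiducials: Optional[FiducialMap] = None,
    min_beats: int = 5,
    min_corr: float = 0.90,
) -> pd.Series | Exclusion:
    """One record's 289-feature row, or an :class:`Exclusion`.

    ``fiducials`` may be supplied (e.g. from an external delineator); when
    absent the built-in delineation is run.
    """
    if fiducials is None:
        try:
            r_peaks = detect_r_peaks(record.lead("II"), record.fs)
        except NoBeatsError as exc:
            return Exclusion(record.record_id, f"no beats: {exc}")
        fiducials = delineate_waves(record, r_peaks)
    templates = build_templates(record, fiducials, min_beats=min_beats,
                                min_corr=min_corr)
    if isinstance(templates, Exclusion):
        return templates

    morph = extract_morphology(record, fiducials)
    hermite = {lead: fit_template_qrs(tpl)
               for lead, tpl in templates.templates.items()}
    ens = ensemble_from_templates(templates.templates)
    v_idx = np.nan
    if ens is not None:
        try:
            v_idx = compute_v_index(ens).v_index_ms
        except Exception:  # degenerate ensembles yield a missing V-index
            logger.warning("%s: V-index undefined", record.record_id)
    return assemble_feature_vector(morph, hermite, v_idx)


def extract_features(
    records: Sequence[EcgRecord],
    fiducials: Optional[Sequence[FiducialMap]] = None,
    min_beats: int = 5,
    min_corr: float = 0.90,
) -> ExtractionResult:
    """Feature matrix over a cohort; QC-excluded records are reported, not kept."""
    rows, ids, labels = [], [], []
    exclusions: list[Exclusion] = []
    for i, rec in enumerate(records):
        fid = fiducials[i] if fiducials is not None else None
        out = extract_record_features(rec, fid, min_beats=min_beats,
                                      min_corr=min_corr)
        if isinstance(out, Exclusion):
            logger.info("excluded %s: %s", out.record_id, out.reason)
            exclusions.append(out)
            continue
        rows.append(out)
        ids.append(rec.record_id)
        labels.append(rec.label)
    if rows:
        values = pd.DataFrame(rows, index=ids)
    else:
        values = pd.DataFrame()
    fm = FeatureMatrix(values=values,
                       labels=pd.Series(labels, index=ids, dtype=object))
    return ExtractionResult(features=fm, exclusions=exclusions)


def median_qrs_duration_ms(row: pd.Series) -> float:
    """Median of the per-lead QRS durations in a feature row."""
    vals = [row.get(f"QRS_dur_{lead}", np.nan) for lead in STANDARD_LEADS]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.median(vals)) if vals else np.nan
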