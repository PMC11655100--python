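"""Core in-memory containers for 12-lead ECG records and fiducial maps.

Amplitudes are millivolts everywhere inside the library; conversion to the
clinical millimetre scale (10 mm/mV) happens only in :mod:`ecglvh.criteria`.
Sample indices are 0-based and windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: The twelve standard leads, in the fixed internal order.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LIMB_LEADS: tuple[str, ...] = ("I", "II", "III", "aVR", "aVL", "aVF")
PRECORDIAL_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")

#: Beat landmarks in temporal order. ``J`` is the QRS offset.
LANDMARKS: tuple[str, ...] = (
    "P_on", "P_peak", "P_off",
    "QRS_on", "Q", "R", "S", "J",
    "T_on", "T_peak", "T_off",
)

CONTROL = "control"
LVH = "lvh"
UNKNOWN = "unknown"


class EcgLvhError(Exception):
    """Base class for package errors."""


class ConfigurationError(EcgLvhError):
    """Invalid configuration (lead set, sampling rate, ...)."""


class NoBeatsError(EcgLvhError):
    """R-peak detection found no usable beats (e.g. flat signal)."""


@dataclass
class EcgRecord:
    """A 12-lead ECG record.

    Parameters
    ----------
    record_id : str
        Identifier of the record.
    signals : ndarray, shape (12, n_samples)
        Lead signals in mV, rows ordered as :data:`STANDARD_LEADS`.
    fs : float
        Sampling rate in Hz.
    label : str
        ``"control"``, ``"lvh"`` or ``"unknown"``.
    """

    record_id: str
    signals: np.ndarray
    fs: float
    label: str = UNKNOWN
    lead_names: tuple[str, ...] = STANDARD_LEADS

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if tuple(self.lead_names) != STANDARD_LEADS:
            raise ConfigurationError(
                f"leads must be exactly {STANDARD_LEADS}, got {self.lead_names}"
            )
        if self.signals.ndim != 2 or self.signals.shape[0] != 12:
            raise ConfigurationError(
                f"signals must be 12 x N, got shape {self.signals.shape}"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ConfigurationError("signals contain non-finite samples")
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if self.label not in (CONTROL, LVH, UNKNOWN):
            raise ConfigurationError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (mV)."""
        return self.signals[STANDARD_LEADS.index(name)]


@dataclass
class BeatFiducials:
    """Landmark sample indices for one beat on one lead.

    Absent landmarks are ``None`` (never fabricated). ``baseline_mv`` is the
    isoelectric reference for the beat, measured on the PR segment.
    """

    P_on: Optional[int] = None
    P_peak: Optional[int] = None
    P_off: Optional[int] = None
    QRS_on: Optional[int] = None
    Q: Optional[int] = None
    R: Optional[int] = None
    S: Optional[int] = None
    J: Optional[int] = None
    T_on: Optional[int] = None
    T_peak: Optional[int] = None
    T_off: Optional[int] = None
    baseline_mv: float = 0.0

    def get(self, landmark: str) -> Optional[int]:
        return getattr(self, landmark)

    def present(self) -> list[str]:
        return [lm for lm in LANDMARKS if getattr(self, lm) is not None]

    def is_monotone(self) -> bool:
        """Present landmarks must be strictly increasing in temporal order."""
        idx = [getattr(self, lm) for lm in LANDMARKS if getattr(self, lm) is not None]
        return all(a < b for a, b in zip(idx, idx[1:]))


@dataclass
class FiducialMap:
    """Per-lead, per-beat fiducial landmarks for a record."""

    beats: dict[str, list[BeatFiducials]] = field(default_factory=dict)
    n_samples: int = 0

    def validate(self) -> None:
        for lead, beat_list in self.beats.items():
            if lead not in STANDARD_LEADS:
                raise ConfigurationError(f"unknown lead {lead!r}")
            for i, b in enumerate(beat_list):
                if b.R is None:
                    raise ConfigurationError(f"{lead} beat {i}: R must be present")
                if not b.is_monotone():
                    raise ConfigurationError(
                        f"{lead} beat {i}: landmarks not strictly increasing"
                    )
                for lm in b.present():
                    v = b.get(lm)
                    if not (0 <= v < self.n_samples):
                        raise ConfigurationError(
                            f"{lead} beat {i}: {lm}={v} outside record"
                        )

    def n_beats(self, lead: str) -> int:
        return len(self.beats.get(lead, []))

    def to_frame(self, record_id: str) -> pd.DataFrame:
        """Long-format table ``record_id, lead, beat, landmark, sample_index``."""
        rows = []
        for lead in STANDARD_LEADS:
            for i, b in enumerate(self.beats.get(lead, [])):
                for lm in b.present():
                    rows.append((record_id, lead, i, lm, b.get(lm)))
        return pd.DataFrame(
            rows, columns=["record_id", "lead", "beat", "landmark", "sample_index"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_samples: int) -> "FiducialMap":
        fm = cls(n_samples=n_samples)
        for lead, sub in df.groupby("lead"):
            n = int(sub["beat"].max()) + 1
            beats = [BeatFiducials() for _ in range(n)]
            for _, row in sub.iterrows():
                setattr(beats[int(row["beat"])], row["landmark"], int(row["sample_index"]))
            fm.beats[str(lead)] = beats
        return fm


def check_labels(labels: Iterable[str]) -> np.ndarray:
    labels = np.asarray(list(labels), dtype=object)
    bad = set(labels) - {CONTROL, LVH, UNKNOWN}
    if bad:
        raise ConfigurationError(f"unknown labels: {sorted(bad)}")
    return labels


# names of the landmark fields, for CSV import/export convenience
_BEAT_FIELDS = tuple(f.name for f in dc_fields(BeatFiducials))
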