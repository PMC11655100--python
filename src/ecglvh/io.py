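"""Record and table I/O: WFDB header/signal pairs, label files, feature CSVs.

The WFDB support here is a deliberately small reader/writer for the subset of
the format the 12-lead databases on PhysioNet use: a text ``.hea`` header plus
a single format-16 (little-endian int16, interleaved) ``.dat`` signal file,
with per-lead gain/baseline/units. Signals are converted to mV on read using
the header metadata and reordered to the standard lead order.
"""

from __future__ import annotations

import ast
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    CONTROL,
    LVH,
    STANDARD_LEADS,
    ConfigurationError,
    EcgRecord,
    EcgLvhError,
)


class IoError(EcgLvhError):
    """Unreadable or malformed file."""


_UNIT_TO_MV = {"mV": 1.0, "uV": 1e-3, "V": 1e3, "mv": 1.0, "uv": 1e-3}

# SNOMED-CT codes used by the 12-lead challenge label files
SNOMED_LVH = "164873001"
SNOMED_NORM = "426783006"


# ---------------------------------------------------------------------------
# WFDB record I/O


def write_wfdb_record(record: EcgRecord, directory: str, gain: float = 1000.0) -> str:
    """Write ``record`` as a WFDB header + format-16 signal pair.

    Returns the record path (without extension). Samples are digitized as
    ``round(mV * gain)`` int16 with zero baseline, units mV.
    """
    os.makedirs(directory, exist_ok=True)
    name = record.record_id
    n_sig, n_samp = record.signals.shape
    dat_name = f"{name}.dat"
    raw = np.clip(np.round(record.signals * gain), -32768, 32767).astype("<i2")
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for i, lead in enumerate(record.lead_names):
        first = int(raw[i, 0])
        checksum = int(np.sum(raw[i], dtype=np.int64) % 65536)
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    with open(os.path.join(directory, f"{name}.hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # format 16: samples interleaved across signals, little-endian int16
    raw.T.reshape(-1).tofile(os.path.join(directory, dat_name))
    return os.path.join(directory, name)


def _parse_signal_spec(line: str) -> dict:
    parts = line.split()
    if len(parts) < 3:
        raise IoError(f"malformed signal line: {line!r}")
    spec = {"file": parts[0], "fmt": parts[1]}
    gain_field = parts[2]
    # adc_gain(baseline)/units — all three parts optional in the format
    units = "mV"
    baseline = 0.0
    if "/" in gain_field:
        gain_field, units = gain_field.split("/", 1)
    if "(" in gain_field:
        gain_field, rest = gain_field.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(gain_field) if gain_field else 200.0
    if gain == 0:
        gain = 200.0
    spec.update(gain=gain, baseline=baseline, units=units)
    # description (lead name) is the trailing free-text field
    spec["description"] = parts[8] if len(parts) >= 9 else ""
    return spec


def read_wfdb_record(path: str, label: str = "unknown") -> EcgRecord:
    """Read a WFDB header/signal pair into an :class:`EcgRecord` (mV).

    ``path`` is the record path with or without the ``.hea`` extension.
    Leads are reordered to the standard order; a missing standard lead or an
    unconvertible unit raises :class:`IoError`.
    """
    if path.endswith(".hea"):
        path = path[:-4]
    hea_path = path + ".hea"
    if not os.path.exists(hea_path):
        raise IoError(f"no such header file: {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise IoError(f"malformed header line: {lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samp = int(head[3])
    specs = [_parse_signal_spec(ln) for ln in lines[1 : 1 + n_sig]]
    if len(specs) != n_sig:
        raise IoError("header declares more signals than it describes")
    if any(s["fmt"] != "16" for s in specs):
        raise IoError("only WFDB format 16 is supported")
    dat_files = {s["file"] for s in specs}
    if len(dat_files) != 1:
        raise IoError("multi-file records are not supported")
    raw = np.fromfile(os.path.join(os.path.dirname(hea_path), specs[0]["file"]),
                      dtype="<i2")
    if raw.size < n_sig * n_samp:
        raise IoError("signal file shorter than header declares")
    mat = raw[: n_sig * n_samp].reshape(n_samp, n_sig).T.astype(float)

    by_lead: dict[str, np.ndarray] = {}
    for i, s in enumerate(specs):
        unit = s["units"].strip()
        if unit not in _UNIT_TO_MV:
            raise IoError(f"cannot convert unit {unit!r} to mV")
        # description may be e.g. "V1" or "lead V1"; match on last token
        lead = s["description"].split()[-1] if s["description"] else ""
        by_lead[lead] = (mat[i] - s["baseline"]) / s["gain"] * _UNIT_TO_MV[unit]
    missing = [ld for ld in STANDARD_LEADS if ld not in by_lead]
    if missing:
        raise IoError(f"record {path}: missing leads {missing}")
    signals = np.vstack([by_lead[ld] for ld in STANDARD_LEADS])
    return EcgRecord(record_id=os.path.basename(path), signals=signals,
                     fs=fs, label=label)


# ---------------------------------------------------------------------------
# Label files


def load_labels(path: str, dialect: str = "plain_csv") -> dict[str, str]:
    """Load ``record_id -> label`` maps from a label file.

    Dialects: ``plain_csv`` (columns record_id,label); ``ptbxl_scp`` (columns
    ecg_id,scp_codes with a stringified code→likelihood dict); and
    ``challenge_snomed`` (columns record_id,dx with comma-separated SNOMED
    codes). A record carrying the LVH code maps to ``lvh`` even if NORM is
    also present; NORM-only records map to ``control``; everything else is
    dropped.
    """
    if not os.path.exists(path):
        raise IoError(f"no such file: {path}")
    if dialect == "plain_csv":
        df = pd.read_csv(path, dtype=str)
        _require_cols(df, ["record_id", "label"], path)
        out = {}
        for rid, lab in zip(df["record_id"], df["label"]):
            if lab in (CONTROL, LVH):
                out[str(rid)] = lab
        return out
    if dialect == "ptbxl_scp":
        df = pd.read_csv(path, dtype=str)
        _require_cols(df, ["ecg_id", "scp_codes"], path)
        out = {}
        for rid, codes in zip(df["ecg_id"], df["scp_codes"]):
            try:
                code_map = ast.literal_eval(codes)
            except (ValueError, SyntaxError) as exc:
                raise IoError(f"malformed scp_codes for {rid}: {codes!r}") from exc
            if "LVH" in code_map:
                out[str(rid)] = LVH
            elif "NORM" in code_map:
                out[str(rid)] = CONTROL
        return out
    if dialect == "challenge_snomed":
        df = pd.read_csv(path, dtype=str)
        _require_cols(df, ["record_id", "dx"], path)
        out = {}
        for rid, dx in zip(df["record_id"], df["dx"]):
            codes = {c.strip() for c in str(dx).split(",")}
            if SNOMED_LVH in codes:
                out[str(rid)] = LVH
            elif SNOMED_NORM in codes:
                out[str(rid)] = CONTROL
        return out
    raise IoError(f"unknown label dialect {dialect!r}")


def _require_cols(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise IoError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Feature matrices


@dataclass
class FeatureMatrix:
    """Records × named features, with aligned labels.

    ``values`` is a DataFrame indexed by record_id with one column per
    feature; column names follow the ``<feature>_<lead>`` convention plus the
    lead-independent ``v_index``.
    """

    values: pd.DataFrame
    labels: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = pd.Series(
                ["unknown"] * len(self.values), index=self.values.index
            )
        self.labels = self.labels.reindex(self.values.index)
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ConfigurationError(f"duplicate feature columns: {dup}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ConfigurationError(f"duplicate record ids: {dup}")
        if len(self.values) and self.values.isna().all(axis=1).any():
            bad = self.values.index[self.values.isna().all(axis=1)].tolist()
            raise ConfigurationError(f"records with all-missing features: {bad}")

    @property
    def record_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.values)


def write_feature_matrix(fm: FeatureMatrix, path: str) -> None:
    """CSV with header ``record_id,label,<feature columns...>``; NaN → empty."""
    out = fm.values.copy()
    out.insert(0, "label", fm.labels)
    out.index.name = "record_id"
    out.to_csv(path, na_rep="")


def read_feature_matrix(path: str) -> FeatureMatrix:
    df = pd.read_csv(path, dtype={"record_id": str})
    _require_cols(df, ["record_id", "label"], path)
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
        raise IoError(f"{path}: duplicated record_id(s) {dup}")
    df = df.set_index("record_id")
    labels = df.pop("label").astype(str)
    return FeatureMatrix(values=df.astype(float), labels=labels)
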