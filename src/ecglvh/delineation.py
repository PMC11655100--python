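"""Beat detection, fiducial-point delineation, beat templates and quality control.

R peaks are detected on lead II with a Pan-Tompkins-style transform
(band-pass, differentiate, square, moving-window integrate, adaptive
threshold) and reused as beat anchors on every lead. Per-lead wave landmarks
are then located by windowed extremum searches around each anchor, with
onsets/offsets found where the signal returns to within a tolerance band of
the local baseline (1% of the wave's own amplitude, with a noise floor).

Quality control mirrors standard template-based practice: beats are aligned
on R, beats poorly correlated with the per-lead median beat are dropped, and
a record without a minimum number of coherent beats on every lead is excluded
(exclusion is a reported outcome, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .records import (
    STANDARD_LEADS,
    BeatFiducials,
    EcgRecord,
    FiducialMap,
    NoBeatsError,
)

#: fraction of a wave's peak amplitude defining its onset/offset crossing
ONSET_FRACTION = 0.01
#: minimum |amplitude| (mV) for a wave to be considered present
MIN_WAVE_AMP_MV = 0.025
#: refractory period between R peaks
REFRACTORY_S = 0.200


def _ms(fs: float, ms: float) -> int:
    return max(1, int(round(fs * ms / 1000.0)))


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """Light Savitzky-Golay smoothing (~14 ms window) for landmark searches."""
    win = _ms(fs, 14)
    if win % 2 == 0:
        win += 1
    if win < 5:
        win = 5
    if len(x) <= win:
        return x.copy()
    return sps.savgol_filter(x, win, 3)


def _noise_sd(x: np.ndarray, smoothed: np.ndarray) -> float:
    """Robust estimate of additive noise from the smoothing residual."""
    resid = x - smoothed
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak sample indices on a single lead.

    Polarity-invariant (the detection statistic is squared); peaks are
    refined to the extremum of the raw signal so that, on clean signals, the
    returned index matches the true peak to within a sample.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise NoBeatsError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        raise NoBeatsError("flat signal")

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(18.0, 0.9 * nyq) / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = _ms(fs, 150)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = _ms(fs, 1000 * REFRACTORY_S)
    cand, props = sps.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        raise NoBeatsError("no candidate beats")
    heights = integ[cand]
    # adaptive threshold: a fraction of the typical strong-peak height
    strong = np.percentile(heights, 90)
    thr = 0.20 * strong
    cand = cand[heights >= thr]
    if len(cand) == 0:
        raise NoBeatsError("no beats above threshold")

    med = np.median(x)
    half = _ms(fs, 60)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        r = lo + int(np.argmax(np.abs(x[lo:hi] - med)))
        peaks.append(r)
    # dedupe refined peaks inside the refractory window, keep the larger
    peaks = sorted(set(peaks))
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < refractory:
            if abs(x[p] - med) > abs(x[out[-1]] - med):
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=int)


def _nearest_peak(d: np.ndarray, lo: int, hi: int, anchor: int,
                  min_amp: float) -> Optional[int]:
    """Most anchor-proximal local extremum of |d| in [lo, hi) above min_amp."""
    seg = np.abs(d[lo:hi])
    if len(seg) == 0:
        return None
    idx, _ = sps.find_peaks(seg, height=min_amp)
    if len(idx) == 0:
        j = int(np.argmax(seg))
        return lo + j if seg[j] >= min_amp else None
    best = min(idx, key=lambda i: (abs(lo + i - anchor), -seg[i]))
    return lo + int(best)


def _walk_to_baseline(d: np.ndarray, start: int, direction: int, amp: float,
                      floor: float, max_steps: int, run: int = 3) -> int:
    """Walk from a wave peak until the signal settles inside the tolerance band.

    The crossing must hold for ``run`` consecutive samples so that brief
    notches between overlapping waves (e.g. a small Q buried under the R
    upstroke) are walked through rather than mistaken for the baseline.
    """
    thr = max(ONSET_FRACTION * abs(amp), floor)
    i = start
    best, best_val = start, abs(d[start])
    in_band = 0
    for _ in range(max_steps):
        j = i + direction
        if j < 0 or j >= len(d):
            break
        i = j
        v = abs(d[i])
        if v < best_val:
            best, best_val = i, v
        if v <= thr:
            in_band += 1
            if in_band >= run:
                return i - direction * (run - 1)
        else:
            in_band = 0
    return best  # never settled: closest approach to baseline


def _signed_extremum(d: np.ndarray, lo: int, hi: int, sign: float) -> tuple[int, float]:
    seg = sign * d[lo:hi]
    j = int(np.argmax(seg))
    return lo + j, float(seg[j])


def delineate_waves(record: EcgRecord, r_peaks: np.ndarray) -> FiducialMap:
    """Locate P/QRS/T landmarks on every lead using R anchors from lead II.

    Windows (relative to landmarks, at any fs): Q and S as opposite-polarity
    extrema within ±80 ms of R; P peak in [R−300, R−100] ms; T peak as the
    largest-|amplitude| extremum in [J+80, J+420] ms; onsets/offsets by the
    1%-of-peak baseline-return rule. Absent waves are flagged, never
    fabricated; beats whose search windows exceed the record are skipped.
    """
    fs = record.fs
    anchors = np.asarray(r_peaks, dtype=int)
    fm = FiducialMap(n_samples=record.n_samples)
    for lead in STANDARD_LEADS:
        raw = record.lead(lead)
        d = _smooth(raw, fs)
        noise = _noise_sd(raw, d)
        floor = 1.5 * noise
        d = d - _lead_baseline(d, anchors, fs)
        beats = []
        for anchor in anchors:
            b = _delineate_beat(d, raw, fs, int(anchor), floor)
            if b is not None:
                beats.append(b)
        fm.beats[lead] = beats
    fm.validate()
    return fm


def _lead_baseline(d: np.ndarray, anchors: np.ndarray, fs: float) -> float:
    """Isoelectric level from the quiet segment well before each R peak.

    The whole-signal median is biased by wave tails; the window 320-240 ms
    before R sits between the previous T offset and the P onset at usual
    heart rates.
    """
    chunks = []
    for a in anchors:
        lo, hi = a - _ms(fs, 320), a - _ms(fs, 240)
        if lo >= 0:
            chunks.append(d[lo:hi])
    if not chunks:
        return float(np.median(d))
    return float(np.median(np.concatenate(chunks)))


def _delineate_beat(d: np.ndarray, raw: np.ndarray, fs: float, anchor: int,
                    floor: float) -> Optional[BeatFiducials]:
    n = len(d)
    w40, w80 = _ms(fs, 40), _ms(fs, 80)
    if anchor - _ms(fs, 300) < 0 or anchor + _ms(fs, 500) >= n:
        return None  # windows exceed record bounds: skip beat

    b = BeatFiducials()
    # R: anchor-proximal extremum within ±40 ms
    r = _nearest_peak(d, anchor - w40, anchor + w40 + 1, anchor, MIN_WAVE_AMP_MV)
    if r is None:
        return None
    b.R = r
    pol = 1.0 if d[r] >= 0 else -1.0

    # Q and S: opposite-polarity extrema in ±80 ms around R
    gap = max(2, _ms(fs, 4))
    q_idx, q_amp = _signed_extremum(d, max(0, r - w80), r - gap, -pol)
    if q_amp >= MIN_WAVE_AMP_MV:
        b.Q = q_idx
    s_idx, s_amp = _signed_extremum(d, r + gap, min(n, r + w80 + 1), -pol)
    if s_amp >= MIN_WAVE_AMP_MV:
        b.S = s_idx

    # QRS onset / J point by outward baseline-return walk
    on_from = b.Q if b.Q is not None else r
    on_amp = d[on_from]
    b.QRS_on = _walk_to_baseline(d, on_from, -1, on_amp, floor, _ms(fs, 80))
    j_from = b.S if b.S is not None else r
    b.J = _walk_to_baseline(d, j_from, +1, d[j_from], floor, _ms(fs, 80))

    # P wave in [R−300, R−100] ms
    p_lo, p_hi = r - _ms(fs, 300), r - _ms(fs, 100)
    p_seg = np.abs(d[p_lo:p_hi])
    p_idx = p_lo + int(np.argmax(p_seg))
    if np.abs(d[p_idx]) >= MIN_WAVE_AMP_MV:
        b.P_peak = p_idx
        b.P_on = _walk_to_baseline(d, p_idx, -1, d[p_idx], floor, _ms(fs, 120))
        b.P_off = _walk_to_baseline(d, p_idx, +1, d[p_idx], floor, _ms(fs, 120))

    # T wave in [J+80, J+420] ms; largest |amplitude|, sign preserved
    t_lo, t_hi = b.J + _ms(fs, 80), min(n, b.J + _ms(fs, 420))
    if t_hi - t_lo > 2:
        t_seg = np.abs(d[t_lo:t_hi])
        t_idx = t_lo + int(np.argmax(t_seg))
        if np.abs(d[t_idx]) >= MIN_WAVE_AMP_MV:
            b.T_peak = t_idx
            b.T_on = _walk_to_baseline(d, t_idx, -1, d[t_idx], floor, _ms(fs, 250))
            b.T_off = _walk_to_baseline(d, t_idx, +1, d[t_idx], floor, _ms(fs, 250))

    # beat baseline: median of the 40 ms PR-segment window ending 20 ms
    # before QRS onset
    bl_hi = b.QRS_on - _ms(fs, 20)
    bl_lo = bl_hi - _ms(fs, 40)
    if bl_lo >= 0 and bl_hi > bl_lo:
        b.baseline_mv = float(np.median(raw[bl_lo:bl_hi]))

    _enforce_monotone(b)
    return b if b.is_monotone() else None


def _enforce_monotone(b: BeatFiducials) -> None:
    """Drop optional landmarks that violate the temporal ordering."""
    if b.P_off is not None and b.QRS_on is not None and b.P_off >= b.QRS_on:
        b.P_off = None
    if b.P_peak is not None and b.QRS_on is not None and b.P_peak >= b.QRS_on:
        b.P_on = b.P_peak = b.P_off = None
    if b.P_on is not None and b.P_peak is not None and b.P_on >= b.P_peak:
        b.P_on = None
    if b.Q is not None and b.QRS_on is not None and b.QRS_on >= b.Q:
        b.QRS_on = None
    if b.S is not None and b.J is not None and b.J <= b.S:
        b.J = None
    if b.T_on is not None and b.J is not None and b.T_on <= b.J:
        b.T_on = None
    if b.T_on is not None and b.T_peak is not None and b.T_on >= b.T_peak:
        b.T_on = None
    if b.T_off is not None and b.T_peak is not None and b.T_off <= b.T_peak:
        b.T_off = None


# ---------------------------------------------------------------------------
# Templates and quality control


@dataclass
class LeadTemplate:
    """Averaged beat for one lead, aligned on R.

    Landmark fields are sample indices *within the template window* (median
    offsets of the retained beats).
    """

    samples: np.ndarray
    fs: float
    r_index: int
    n_beats_used: int
    correlations: np.ndarray
    qrs_on: int
    j: int
    t_on: Optional[int]
    t_peak: Optional[int]
    t_off: Optional[int]
    baseline_mv: float


@dataclass
class Exclusion:
    """A record excluded by quality control, with a reason code."""

    record_id: str
    reason: str

    excluded: bool = True


@dataclass
class TemplateSet:
    record_id: str
    templates: dict[str, LeadTemplate] = field(default_factory=dict)

    excluded: bool = False


def _median_offset(beats: list[BeatFiducials], landmark: str) -> Optional[int]:
    offs = [b.get(landmark) - b.R for b in beats if b.get(landmark) is not None]
    if not offs:
        return None
    return int(round(float(np.median(offs))))


def build_templates(
    record: EcgRecord,
    fiducials: FiducialMap,
    min_beats: int = 5,
    min_corr: float = 0.90,
) -> TemplateSet | Exclusion:
    """Build per-lead averaged-beat templates with beat quality control.

    Beats are aligned on R over a window spanning QRS_on − 150 ms to
    T_off + 50 ms of the median beat. Beats whose correlation with the
    per-lead median beat is below ``min_corr`` are dropped; a lead with fewer
    than ``min_beats`` retained beats excludes the whole record.
    """
    out = TemplateSet(record_id=record.record_id)
    fs = record.fs
    for lead in STANDARD_LEADS:
        beats = fiducials.beats.get(lead, [])
        if len(beats) < min_beats:
            return Exclusion(record.record_id, f"{lead}: only {len(beats)} beats")
        qrs_on_off = _median_offset(beats, "QRS_on")
        t_off_off = _median_offset(beats, "T_off")
        j_off = _median_offset(beats, "J")
        if qrs_on_off is None or j_off is None:
            return Exclusion(record.record_id, f"{lead}: QRS bounds not found")
        if t_off_off is None:
            t_off_off = j_off + _ms(fs, 300)
        lo = qrs_on_off - _ms(fs, 150)
        hi = t_off_off + _ms(fs, 50)
        x = record.lead(lead)
        rows, kept_beats = [], []
        for b in beats:
            a, z = b.R + lo, b.R + hi
            if a < 0 or z > len(x):
                continue
            rows.append(x[a:z] - b.baseline_mv)
            kept_beats.append(b)
        if len(rows) < min_beats:
            return Exclusion(record.record_id, f"{lead}: only {len(rows)} in-bounds beats")
        mat = np.vstack(rows)
        median_beat = np.median(mat, axis=0)
        mb = median_beat - median_beat.mean()
        denom_m = np.linalg.norm(mb)
        corrs = np.zeros(len(rows))
        for i, row in enumerate(mat):
            rc = row - row.mean()
            den = np.linalg.norm(rc) * denom_m
            corrs[i] = 1.0 if den == 0 else float(rc @ mb) / den
        keep = corrs >= min_corr
        if keep.sum() < min_beats:
            return Exclusion(
                record.record_id,
                f"{lead}: {int(keep.sum())} beats pass correlation QC",
            )
        template = mat[keep].mean(axis=0)
        r_index = -lo
        retained = [b for b, k in zip(kept_beats, keep) if k]
        t_on = _median_offset(retained, "T_on")
        t_peak = _median_offset(retained, "T_peak")
        t_off = _median_offset(retained, "T_off")
        bl_hi = r_index + qrs_on_off - _ms(fs, 20)
        bl_lo = bl_hi - _ms(fs, 40)
        baseline = float(np.median(template[max(0, bl_lo):bl_hi])) if bl_hi > 0 else 0.0
        out.templates[lead] = LeadTemplate(
            samples=template,
            fs=fs,
            r_index=r_index,
            n_beats_used=int(keep.sum()),
            correlations=corrs[keep],
            qrs_on=r_index + qrs_on_off,
            j=r_index + j_off,
            t_on=None if t_on is None else r_index + t_on,
            t_peak=None if t_peak is None else r_index + t_peak,
            t_off=None if t_off is None else r_index + t_off,
            baseline_mv=baseline,
        )
    return out
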