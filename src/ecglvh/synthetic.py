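"""Seedable synthetic 12-lead ECG generator with analytic ground truth.

Each beat on each lead is a sum of five Gaussian-shaped waves (P, Q, R, S, T);
the T wave may be asymmetric (different ascending/descending half-widths).
Because every wave is analytic, the generator can emit the exact fiducial
landmarks of every beat, which makes all downstream stages testable without
real recordings.

Two classes are generated. The ``control`` class uses population-typical
amplitudes. The ``lvh`` class applies a voltage/strain-pattern shift: taller
lateral R waves (V5, V6, I, aVL), deeper anterior S waves (V1, V2), T-wave
inversion in V5/V6 and a wider QRS complex — the pattern that clinical
voltage criteria target.

Wave onsets/offsets are defined at the point where the wave reaches 1% of its
peak amplitude; for a Gaussian of half-width ``w`` that is ``±w·√(2·ln 100)``
(≈ 3.03 w) from the centre.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .records import (
    CONTROL,
    LVH,
    STANDARD_LEADS,
    BeatFiducials,
    ConfigurationError,
    EcgRecord,
    FiducialMap,
)

#: Onset/offset threshold as a fraction of peak amplitude.
ONSET_FRACTION = 0.01
#: Half-width multiplier where a Gaussian reaches ONSET_FRACTION of its peak.
ONSET_K = float(np.sqrt(2.0 * np.log(1.0 / ONSET_FRACTION)))  # ≈ 3.035

WAVES = ("P", "Q", "R", "S", "T")


@dataclass
class WaveParams:
    """One Gaussian wave: amplitude (mV), centre relative to R (s), half-width (s).

    ``width_des_s`` (if set) makes the wave asymmetric: the ascending limb uses
    ``width_s`` and the descending limb ``width_des_s``.
    """

    amp_mv: float
    center_s: float
    width_s: float
    width_des_s: Optional[float] = None

    @property
    def w_des(self) -> float:
        return self.width_des_s if self.width_des_s is not None else self.width_s


@dataclass
class ClassShift:
    """Additive deltas applied to the control parameters for the LVH class."""

    #: additive amplitude deltas, keyed (lead, wave), in mV
    amp_delta_mv: dict[tuple[str, str], float] = field(default_factory=dict)
    #: leads whose T amplitude sign is flipped (strain-pattern inversion)
    t_flip_leads: tuple[str, ...] = ()
    #: widening of the QRS onset-to-offset span, in seconds
    qrs_widen_s: float = 0.0


# Control-class wave parameters, loosely modelled on population-typical
# 12-lead amplitudes (mV). Timing shared across leads: P at −170 ms,
# Q at −40 ms, R at 0, S at +40 ms, T at +300 ms relative to the R peak.
def _w(amp, center, width, width_des=None) -> WaveParams:
    return WaveParams(amp, center, width, width_des)


def _default_lead_params() -> dict[str, dict[str, WaveParams]]:
    amps = {
        #        P      Q      R      S      T
        "I":   (0.08, -0.05, 0.70, -0.15, 0.25),
        "II":  (0.12, -0.06, 1.00, -0.20, 0.30),
        "III": (0.06, -0.04, 0.50, -0.15, 0.15),
        "aVR": (-0.08, 0.05, -0.60, 0.15, -0.25),
        "aVL": (0.06, -0.04, 0.35, -0.10, 0.12),
        "aVF": (0.09, -0.05, 0.75, -0.17, 0.20),
        "V1":  (0.05, -0.03, 0.25, -0.90, 0.15),
        "V2":  (0.06, -0.03, 0.40, -1.10, 0.30),
        "V3":  (0.06, -0.04, 0.80, -0.80, 0.35),
        "V4":  (0.07, -0.05, 1.40, -0.50, 0.35),
        "V5":  (0.08, -0.06, 1.50, -0.30, 0.30),
        "V6":  (0.08, -0.05, 1.20, -0.20, 0.25),
    }
    out: dict[str, dict[str, WaveParams]] = {}
    for lead, (p, q, r, s, t) in amps.items():
        out[lead] = {
            "P": _w(p, -0.170, 0.025),
            "Q": _w(q, -0.040, 0.008),
            "R": _w(r, 0.000, 0.012),
            "S": _w(s, 0.040, 0.009),
            "T": _w(t, 0.300, 0.060, 0.045),
        }
    return out


def default_class_shift() -> ClassShift:
    """LVH-like shift: tall lateral R, deep V1/V2 S, lateral T inversion, wider QRS."""
    amp = {(lead, "R"): 0.8 for lead in ("V5", "V6", "I", "aVL")}
    amp.update({(lead, "S"): -0.8 for lead in ("V1", "V2")})
    return ClassShift(amp_delta_mv=amp, t_flip_leads=("V5", "V6"), qrs_widen_s=0.020)


@dataclass
class SyntheticConfig:
    """Generator configuration.

    Defaults emulate 10-second, 500 Hz 12-lead recordings at 60 bpm with
    20 µV additive white noise.
    """

    fs: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.01
    lead_params: dict[str, dict[str, WaveParams]] = field(default_factory=_default_lead_params)
    class_shift: ClassShift = field(default_factory=default_class_shift)
    #: between-record voltage variability: sigma of a shared lognormal
    #: amplitude scale drawn once per record (body-habitus-like effect)
    amp_scale_sd: float = 0.25
    #: per-lead, per-wave multiplicative amplitude jitter (electrode-like)
    lead_amp_jitter_sd: float = 0.10
    noise_sd_mv: float = 0.02
    baseline_wander_mv: float = 0.0
    baseline_wander_hz: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        if self.noise_sd_mv < 0:
            raise ConfigurationError("noise_sd_mv must be >= 0")
        if set(self.lead_params) != set(STANDARD_LEADS):
            raise ConfigurationError(
                f"lead_params must cover exactly {STANDARD_LEADS}"
            )
        for lead, waves in self.lead_params.items():
            for name, wp in waves.items():
                if wp.width_s <= 0 or wp.w_des <= 0:
                    raise ConfigurationError(f"{lead}/{name}: widths must be > 0")


def _shifted_params(config: SyntheticConfig) -> dict[str, dict[str, WaveParams]]:
    """Apply the LVH class shift to a copy of the control parameters."""
    params = copy.deepcopy(config.lead_params)
    shift = config.class_shift
    for (lead, wave), delta in shift.amp_delta_mv.items():
        wp = params[lead][wave]
        params[lead][wave] = replace(wp, amp_mv=wp.amp_mv + delta)
    for lead in shift.t_flip_leads:
        wp = params[lead]["T"]
        params[lead]["T"] = replace(wp, amp_mv=-wp.amp_mv)
    if shift.qrs_widen_s > 0:
        # widen the QRS onset-to-offset span by qrs_widen_s: shift the Q
        # centre earlier and the S centre later by half the widening each,
        # leaving wave shapes (and hence peak overlap) unchanged
        dc = shift.qrs_widen_s / 2.0
        for lead in STANDARD_LEADS:
            q, s = params[lead]["Q"], params[lead]["S"]
            params[lead]["Q"] = replace(q, center_s=q.center_s - dc)
            params[lead]["S"] = replace(s, center_s=s.center_s + dc)
    return params


def _randomize_amplitudes(
    params: dict[str, dict[str, WaveParams]],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, dict[str, WaveParams]]:
    """Between-record amplitude variability.

    A single lognormal scale per record multiplies every wave (the dominant
    inter-subject effect on ECG voltage), plus an independent multiplicative
    jitter per lead and wave. Wave timing, widths and amplitude signs are
    untouched, so the analytic fiducial ground truth is unaffected.
    """
    if config.amp_scale_sd <= 0 and config.lead_amp_jitter_sd <= 0:
        return params
    scale = float(rng.lognormal(0.0, config.amp_scale_sd)) \
        if config.amp_scale_sd > 0 else 1.0
    out: dict[str, dict[str, WaveParams]] = {}
    for lead in STANDARD_LEADS:
        out[lead] = {}
        for wave in WAVES:
            wp = params[lead][wave]
            jitter = 1.0
            if config.lead_amp_jitter_sd > 0:
                # clipped well above zero so signs never flip
                jitter = max(0.3, 1.0 + rng.normal(0.0, config.lead_amp_jitter_sd))
            out[lead][wave] = replace(wp, amp_mv=wp.amp_mv * scale * jitter)
    return out


def _wave_samples(t: np.ndarray, center: float, wp: WaveParams) -> np.ndarray:
    """Evaluate one (possibly asymmetric) Gaussian wave on time grid ``t``."""
    dt = t - center
    w = np.where(dt < 0, wp.width_s, wp.w_des)
    return wp.amp_mv * np.exp(-(dt**2) / (2.0 * w**2))


def generate_record(
    config: SyntheticConfig, label: str, seed: int
) -> tuple[EcgRecord, FiducialMap]:
    """Generate one synthetic record and its ground-truth fiducial map.

    Identical ``(config, label, seed)`` reproduce the output bit-for-bit.
    """
    if label not in (CONTROL, LVH):
        raise ConfigurationError(f"label must be 'control' or 'lvh', got {label!r}")
    rng = np.random.default_rng(seed)
    params = _shifted_params(config) if label == LVH else config.lead_params
    params = _randomize_amplitudes(params, config, rng)

    fs = config.fs
    n = int(round(fs * config.duration_s))
    t = np.arange(n) / fs
    rr_mean = 60.0 / config.heart_rate_bpm

    # beat train: first R placed so the P wave fits; beats kept only while the
    # T wave fits inside the record (edge beats are dropped, not truncated)
    max_t_off = max(
        params[ld]["T"].center_s + ONSET_K * params[ld]["T"].w_des
        for ld in STANDARD_LEADS
    )
    min_p_on = min(
        params[ld]["P"].center_s - ONSET_K * params[ld]["P"].width_s
        for ld in STANDARD_LEADS
    )
    r_times = []
    tt = -min_p_on + 0.02
    while True:
        if tt + max_t_off + 0.02 > config.duration_s:
            break
        r_times.append(tt)
        tt += rr_mean + (rng.normal(0.0, config.rr_jitter_sd_s)
                         if config.rr_jitter_sd_s > 0 else 0.0)

    signals = np.zeros((12, n))
    fm = FiducialMap(n_samples=n)
    for li, lead in enumerate(STANDARD_LEADS):
        lw = params[lead]
        beats = []
        for rt in r_times:
            for wave in WAVES:
                wp = lw[wave]
                if wp.amp_mv != 0.0:
                    # evaluate only within ±6 half-widths of the centre,
                    # where the Gaussian is above ~1e-8 of its peak
                    c = rt + wp.center_s
                    w_max = max(wp.width_s, wp.w_des)
                    lo = max(0, int(np.floor((c - 6 * w_max) * fs)))
                    hi = min(n, int(np.ceil((c + 6 * w_max) * fs)) + 1)
                    signals[li, lo:hi] += _wave_samples(t[lo:hi], c, wp)
            beats.append(_truth_fiducials(lw, rt, fs, n))
        fm.beats[lead] = beats

    if config.baseline_wander_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signals += config.baseline_wander_mv * np.sin(
            2 * np.pi * config.baseline_wander_hz * t + phase
        )
    if config.noise_sd_mv > 0:
        signals += rng.normal(0.0, config.noise_sd_mv, size=signals.shape)

    rec = EcgRecord(record_id=f"syn_{label}_{seed}", signals=signals, fs=fs, label=label)
    fm.validate()
    return rec, fm


def _truth_fiducials(
    lw: dict[str, WaveParams], r_time: float, fs: float, n: int
) -> BeatFiducials:
    """Analytic landmark indices for one beat (1%-of-peak onset/offset rule)."""

    def idx(time_s: float) -> int:
        return int(round(time_s * fs))

    b = BeatFiducials(baseline_mv=0.0)
    p, q, r, s, tw = (lw[w] for w in WAVES)
    if p.amp_mv != 0.0:
        b.P_on = idx(r_time + p.center_s - ONSET_K * p.width_s)
        b.P_peak = idx(r_time + p.center_s)
        b.P_off = idx(r_time + p.center_s + ONSET_K * p.w_des)
    if q.amp_mv != 0.0:
        b.QRS_on = idx(r_time + q.center_s - ONSET_K * q.width_s)
        b.Q = idx(r_time + q.center_s)
    else:
        b.QRS_on = idx(r_time + r.center_s - ONSET_K * r.width_s)
    b.R = idx(r_time + r.center_s)
    if s.amp_mv != 0.0:
        b.S = idx(r_time + s.center_s)
        b.J = idx(r_time + s.center_s + ONSET_K * s.w_des)
    else:
        b.J = idx(r_time + r.center_s + ONSET_K * r.w_des)
    if tw.amp_mv != 0.0:
        b.T_on = idx(r_time + tw.center_s - ONSET_K * tw.width_s)
        b.T_peak = idx(r_time + tw.center_s)
        b.T_off = idx(r_time + tw.center_s + ONSET_K * tw.w_des)
    return b


def generate_cohort(
    n_control: int,
    n_lvh: int,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> tuple[list[EcgRecord], np.ndarray, list[FiducialMap]]:
    """Generate a labelled cohort; per-record seeds are ``seed + index``.

    Returns ``(records, labels, fiducial_maps)`` with the ``n_control``
    control records first.
    """
    if n_control < 0 or n_lvh < 0:
        raise ConfigurationError("cohort sizes must be >= 0")
    if config is None:
        config = SyntheticConfig()
    records: list[EcgRecord] = []
    fiducials: list[FiducialMap] = []
    labels = []
    for i in range(n_control + n_lvh):
        label = CONTROL if i < n_control else LVH
        rec, fm = generate_record(config, label, seed + i)
        rec.record_id = f"syn{i:05d}"
        records.append(rec)
        fiducials.append(fm)
        labels.append(label)
    return records, np.asarray(labels, dtype=object), fiducials
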