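"""V-index: spatial heterogeneity of ventricular repolarization times.

The T waves of the leads are modelled with the dominant-T-wave rank-1 +
derivative expansion: stacking baseline-corrected T-wave segments as the
rows of a matrix ``Psi`` (leads × time),

    Psi_row(i)  ≈  w1(i) · T_d  +  w2(i) · dT_d/dt,

where ``T_d`` is the dominant T-wave common to all leads and the derivative
term captures per-lead time shifts of repolarization (a first-order lag
expansion). Under this model the cross-lead dispersion of the lag
coefficients, normalized by the dispersion of the gains, estimates the
standard deviation of repolarization times across the ventricular myocardium:

    v_index = std[w2] / std[w1]      (seconds; reported in ms).

The index is invariant to a global rescaling of the signals and is
non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import ConfigurationError, EcgLvhError


class DegenerateEnsembleError(EcgLvhError):
    """Rank-0 ensemble or numerically singular regressors."""


#: leads used by default: the 8 linearly independent ones (the augmented
#: limb leads are linear combinations and would bias cross-lead dispersions)
DEFAULT_VINDEX_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class TWaveEnsemble:
    """Baseline-corrected T-wave segments on a common uniform time grid."""

    psi: np.ndarray               #: L × M matrix, mV
    fs: float                     #: sampling rate of the common grid, Hz
    leads: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.psi.shape[0] < 3:
            raise ConfigurationError("need at least 3 leads")
        if self.psi.shape[1] < 20:
            raise ConfigurationError("need at least 20 samples per segment")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")


@dataclass
class VIndexResult:
    v_index_ms: float
    w1: np.ndarray
    w2: np.ndarray
    dominant_t: np.ndarray
    dominant_t_deriv: np.ndarray
    leads: tuple[str, ...] = ()


def dominant_t_wave(ensemble: TWaveEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """First left singular direction of the ensemble, as a time waveform.

    Returns the unit-norm dominant T-wave and its time derivative (central
    differences scaled by ``fs``). The sign is fixed so that the correlation
    of the dominant wave with the mean row is positive.
    """
    psi = ensemble.psi
    if not np.any(psi):
        raise DegenerateEnsembleError("all-zero ensemble")
    # rows are leads; the shared time-domain waveform is the leading right
    # singular vector of Psi
    _, _, vt = np.linalg.svd(psi, full_matrices=False)
    td = vt[0]
    mean_row = psi.mean(axis=0)
    if float(td @ mean_row) < 0:
        td = -td
    dtd = _smooth_derivative(td, ensemble.fs)
    return td, dtd


#: local-polynomial window (s) for smoothing/differentiating the estimated
#: dominant wave; well below the T-wave time scale, wide enough to suppress
#: the high-frequency part of the SVD estimation noise
_SMOOTH_WIN_S = 0.030


def _sg_window(n: int, fs: float) -> Optional[int]:
    win: int = int(round(_SMOOTH_WIN_S * fs))
    if win % 2 == 0:
        win += 1
    win = max(win, 5)
    return win if n > win else None


def _smooth_derivative(td: np.ndarray, fs: float) -> np.ndarray:
    """Time derivative of the dominant wave by Savitzky-Golay differentiation.

    Plain finite differences amplify the high-frequency part of the SVD
    estimation noise by a factor of order ``fs``, which biases the lag
    coefficients; a local-polynomial derivative keeps the estimate stable
    without distorting the wave at clean-signal resolution.
    """
    win = _sg_window(len(td), fs)
    if win is None:
        return np.gradient(td) * fs
    from scipy.signal import savgol_filter

    return savgol_filter(td, win, 3, deriv=1, delta=1.0 / fs)


def _smooth_wave(td: np.ndarray, fs: float) -> np.ndarray:
    win = _sg_window(len(td), fs)
    if win is None:
        return td
    from scipy.signal import savgol_filter

    return savgol_filter(td, win, 3)


def lead_coefficients(
    ensemble: TWaveEnsemble,
    dominant: np.ndarray,
    dominant_deriv: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lead (w1, w2) minimizing ``||row − w1·T_d − w2·dT_d||``."""
    design = np.column_stack([dominant, dominant_deriv])
    gram = design.T @ design
    if np.linalg.cond(gram) > 1e12:
        raise DegenerateEnsembleError("T_d and its derivative are collinear")
    sol = np.linalg.solve(gram, design.T @ ensemble.psi.T)
    return sol[0], sol[1]


def v_index(w1: np.ndarray, w2: np.ndarray) -> float:
    """Cross-lead std of the lag coefficients over the std of the gains, ms.

    Undefined (NaN) when the gains have zero spread.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if len(w1) < 3 or len(w1) != len(w2):
        raise ConfigurationError("need matched coefficients for >= 3 leads")
    s1 = float(np.std(w1, ddof=1))
    s2 = float(np.std(w2, ddof=1))
    if s1 == 0.0:
        return float("nan")
    return 1000.0 * s2 / s1


def compute_v_index(ensemble: TWaveEnsemble) -> VIndexResult:
    """Dominant wave, lead coefficients and V-index for one ensemble.

    The regression uses a locally-smoothed copy of the estimated dominant
    wave: with noisy ensembles the raw SVD estimate carries white estimation
    noise whose leakage into the lag coefficients would inflate the index.
    """
    td, dtd = dominant_t_wave(ensemble)
    td_s = _smooth_wave(td, ensemble.fs)
    w1, w2 = lead_coefficients(ensemble, td_s, dtd)
    return VIndexResult(
        v_index_ms=v_index(w1, w2),
        w1=w1, w2=w2, dominant_t=td, dominant_t_deriv=dtd,
        leads=ensemble.leads,
    )


def ensemble_from_templates(
    templates: dict[str, "LeadTemplate"],  # noqa: F821 - see ecglvh.delineation
    leads: tuple[str, ...] = DEFAULT_VINDEX_LEADS,
) -> Optional[TWaveEnsemble]:
    """Build the T-wave ensemble from lead templates.

    Each lead contributes its template segment from T_on − 10 ms to
    T_off + 10 ms, baseline-corrected and linearly resampled onto a common
    grid (the median segment length). Leads without a delineated T wave are
    skipped; fewer than 3 usable leads yields ``None``.
    """
    segs, used, durations = [], [], []
    for lead in leads:
        tpl = templates.get(lead)
        if tpl is None or tpl.t_on is None or tpl.t_off is None:
            continue
        pad = max(1, int(round(tpl.fs * 0.010)))
        lo = max(0, tpl.t_on - pad)
        hi = min(len(tpl.samples), tpl.t_off + pad)
        if hi - lo < 4:
            continue
        segs.append(tpl.samples[lo:hi] - tpl.baseline_mv)
        durations.append((hi - lo) / tpl.fs)
        used.append(lead)
    if len(segs) < 3:
        return None
    m = int(np.median([len(s) for s in segs]))
    m = max(m, 20)
    grid = np.linspace(0.0, 1.0, m)
    psi = np.vstack([
        np.interp(grid, np.linspace(0.0, 1.0, len(s)), s) for s in segs
    ])
    fs_common = (m - 1) / float(np.median(durations))
    return TWaveEnsemble(psi=psi, fs=fs_common, leads=tuple(used))
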