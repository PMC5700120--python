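"""Systolic-shoulder detection, augmentation index, and linear
forward/backward wave separation.

The shoulder (inflection) of a type-A central pressure wave is located by
the first zero-crossing of the fourth derivative — obtained with a
Savitzky-Golay differentiation filter of polynomial order 6 over 35
points at 1 kHz — between the time of maximum dP/dt and the systolic
peak. The augmentation index is AIx = (peak - shoulder) / pulse pressure.

Wave separation splits simultaneous P and U increments with the local
wave speed c:  dPf = (dP + rho c dU)/2,  dPb = (dP - rho c dU)/2,
cumulated from zero at cycle start, so Pf + Pb = P - P(0) identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._defaults import BLOOD_DENSITY
from .errors import DetectionError, DomainError

__all__ = [
    "AIxResult",
    "WaveSeparationResult",
    "detect_shoulder",
    "augmentation_index",
    "wave_separation",
]

SG_WINDOW = 35
SG_ORDER = 6
SHOULDER_RATE = 1000.0  # Hz the Savitzky-Golay window is defined at
# Harmonic cutoff applied before differentiation: the fourth derivative
# amplifies a ripple of amplitude a at frequency f by a (2 pi f)^4, so
# sub-0.001-mmHg grid-scale solver ripple would otherwise dominate it.
# Physiological pressure content lives below ~25 harmonics of the heart
# rate; 30 Hz keeps every feature of the systolic shoulder.
SHOULDER_LOWPASS_HZ = 30.0


@dataclass(frozen=True)
class AIxResult:
    AIx: float               # dimensionless (AP / PP)
    shoulder_time: float     # s
    shoulder_pressure: float  # Pa (P1)
    peak_pressure: float     # Pa
    pulse_pressure: float    # Pa
    augmented_pressure: float  # Pa


@dataclass(frozen=True)
class WaveSeparationResult:
    Pf: np.ndarray           # Pa, forward component (0 at cycle start)
    Pb: np.ndarray           # Pa, backward component
    Pb_over_Pf: float        # peak-amplitude ratio
    backward_peak_time: float  # s
    forward_peak_time: float   # s


def _resample_to(P: np.ndarray, fs: float, target: float) -> np.ndarray:
    n_new = int(round(P.size * target / fs))
    t_old = np.arange(P.size) / fs
    t_new = np.arange(n_new) / target
    return np.interp(t_new, t_old, P, period=P.size / fs)


def _fourier_lowpass(P: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Gaussian spectral taper, -3 dB at ``cutoff`` Hz (the wave is periodic).

    A smooth rolloff is essential here: a brick-wall cutoff rings (Gibbs)
    and the ringing creates spurious fourth-derivative zero-crossings.
    """
    spec = np.fft.rfft(P)
    freqs = np.fft.rfftfreq(P.size, d=1.0 / fs)
    spec *= np.exp(-math.log(2.0) * (freqs / cutoff) ** 2)
    return np.fft.irfft(spec, n=P.size)


def _sg_cyclic(P: np.ndarray, deriv: int, fs: float) -> np.ndarray:
    """Savitzky-Golay derivative with periodic extension (waves are cyclic)."""
    pad = SG_WINDOW
    ext = np.concatenate([P[-pad:], P, P[:pad]])
    d = savgol_filter(ext, SG_WINDOW, SG_ORDER, deriv=deriv, delta=1.0 / fs)
    return d[pad:-pad]


def detect_shoulder(P: np.ndarray, sampling_rate: float) -> tuple[float, float]:
    """Locate the systolic shoulder; returns (shoulder_time, P1).

    Input waves not sampled at 1 kHz are resampled first so the 35-point
    filter window keeps its 35 ms physical width. Raises
    :class:`DetectionError` when no qualifying fourth-derivative
    zero-crossing exists (non-type-A wave).
    """
    P = np.asarray(P, dtype=float)
    if P.size < SG_WINDOW:
        raise DetectionError("wave shorter than the differentiation window")
    fs = sampling_rate
    if abs(fs - SHOULDER_RATE) > 1e-9:
        P = _resample_to(P, fs, SHOULDER_RATE)
        fs = SHOULDER_RATE
    Pf = _fourier_lowpass(P, fs, SHOULDER_LOWPASS_HZ)
    d1 = _sg_cyclic(Pf, 1, fs)
    d4 = _sg_cyclic(Pf, 4, fs)
    i_peak = int(np.argmax(P))
    i_upstroke = int(np.argmax(d1[:i_peak])) if i_peak > 1 else 0
    lo, hi = i_upstroke + 1, i_peak
    if hi <= lo:
        raise DetectionError("no interval between max upstroke and peak")
    seg = d4[lo:hi + 1]
    sign = np.sign(seg)
    # a genuine shoulder is a positive-to-negative crossing (upstroke
    # flattening before the augmented rise); a smooth single-hump
    # upstroke only crosses negative-to-positive on its way to the peak
    crossings = np.where((sign[:-1] > 0) & (sign[1:] < 0))[0]
    if crossings.size == 0:
        raise DetectionError(
            "no fourth-derivative zero-crossing before the systolic peak "
            "(wave is not type-A)")
    k = int(crossings[0])
    # linear interpolation of the crossing instant
    f = seg[k] / (seg[k] - seg[k + 1])
    t_sh = (lo + k + f) / fs
    p1 = float(np.interp(t_sh * fs, np.arange(P.size), P))
    return t_sh, p1


def augmentation_index(P: np.ndarray, sampling_rate: float) -> AIxResult:
    """Augmentation index of one cycle of a (type-A) pressure wave."""
    P = np.asarray(P, dtype=float)
    t_sh, p1 = detect_shoulder(P, sampling_rate)
    peak = float(P.max())
    pp = peak - float(P.min())
    if pp <= 0:
        raise DetectionError("zero pulse pressure")
    ap = peak - p1
    return AIxResult(AIx=ap / pp, shoulder_time=t_sh, shoulder_pressure=p1,
                     peak_pressure=peak, pulse_pressure=pp,
                     augmented_pressure=ap)


def wave_separation(P: np.ndarray, U: np.ndarray,
                    rho: float = BLOOD_DENSITY,
                    c_local: float = None,
                    sampling_rate: float = 1000.0) -> WaveSeparationResult:
    """Linear separation of P into forward and backward components.

    ``c_local`` is the wave speed used for the split (in the virtual
    setting, the exact theoretical speed at the measurement site). Peak
    amplitudes are referenced to the zero baseline at cycle start.
    """
    if c_local is None or c_local <= 0:
        raise DomainError("wave separation needs a positive local wave speed")
    if rho <= 0:
        raise DomainError("blood density must be > 0")
    P = np.asarray(P, dtype=float)
    U = np.asarray(U, dtype=float)
    if P.shape != U.shape:
        raise DomainError("P and U must have equal length")
    dP = np.diff(P)
    dU = np.diff(U)
    dPf = 0.5 * (dP + rho * c_local * dU)
    dPb = 0.5 * (dP - rho * c_local * dU)
    Pf = np.concatenate(([0.0], np.cumsum(dPf)))
    Pb = np.concatenate(([0.0], np.cumsum(dPb)))
    pf_max = float(Pf.max())
    pb_max = float(Pb.max())
    ratio = pb_max / pf_max if pf_max > 0 else np.nan
    return WaveSeparationResult(
        Pf=Pf, Pb=Pb, Pb_over_Pf=ratio,
        backward_peak_time=float(np.argmax(Pb)) / sampling_rate,
        forward_peak_time=float(np.argmax(Pf)) / sampling_rate)
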