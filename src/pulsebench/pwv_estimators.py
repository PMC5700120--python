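"""Clinical pulse-wave-velocity estimators and their theoretical references.

Five estimators are implemented against the exact tube-law wave speed of
the virtual network:

* foot-to-foot transit time (pressure or flow waves) over a path,
* the three single-site loop methods,

      PWV_PU   = (1/rho) dP/dU
      PWV_QA   = dQ/dA
      PWV_lnDU = (1/2) dU/d(lnD)

  fitted over the linear early-systolic part of the loop,
* the sum-of-squares estimator over one full cycle,

      PWV_SS = (1/rho) sqrt( sum dP^2 / sum dU^2 ).

Bifurcation reflection coefficients use characteristic admittances
Y = A / (rho c):  Rt = (Yp - Yd1 - Yd2) / (Yp + Yd1 + Yd2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._defaults import BLOOD_DENSITY
from .errors import DetectionError, DomainError, EstimationError, StructuralError
from .virtual_cohort import ArterialNetwork, ArterialSegment, segment_wave_speed

__all__ = [
    "FootDetection",
    "PWVEstimate",
    "ReflectionResult",
    "theoretical_pwv",
    "path_theoretical_pwv",
    "detect_foot",
    "foot_to_foot_pwv",
    "loop_pwv",
    "sum_of_squares_pwv",
    "reflection_coefficient",
    "mean_reflection_coefficient",
]


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FootDetection:
    """Foot of a pulse wave by the intersecting-tangent rule."""

    foot_time: float       # s
    max_slope_time: float  # s
    diastolic_min: float   # signal units


@dataclass
class PWVEstimate:
    """One PWV estimate with its matched theoretical reference."""

    method: str
    site_or_path: str
    value: float                 # m/s
    theoretical: float = math.nan  # m/s
    meta: dict = field(default_factory=dict)

    @property
    def relative_error(self) -> float:
        """(value - theoretical) / theoretical (dimensionless)."""
        return (self.value - self.theoretical) / self.theoretical


@dataclass(frozen=True)
class ReflectionResult:
    """Admittance-mismatch reflection coefficient of one bifurcation."""

    bifurcation: tuple[str, str, str]
    Yp: float
    Yd1: float
    Yd2: float
    Rt: float


# --------------------------------------------------------------------------
# theoretical speeds
# --------------------------------------------------------------------------

def theoretical_pwv(segment: ArterialSegment,
                    rho: float = BLOOD_DENSITY) -> float:
    """Moens-Korteweg wave speed at the segment midpoint reference area."""
    return segment_wave_speed(segment, rho, s=0.5)


def path_theoretical_pwv(network: ArterialNetwork, from_site: str,
                         to_site: str, rho: float = BLOOD_DENSITY) -> float:
    """Transit-time-averaged theoretical speed between two sites.

    The sites must lie on one root-to-leaf path with ``to_site``
    downstream. Each traversed segment contributes its (possibly partial)
    length at the segment-midpoint speed:  PWV = sum(L_i) / sum(L_i/c_i).
    """
    seg_a, s_a = network.site_local(from_site)
    seg_b, s_b = network.site_local(to_site)
    chain = network.path_segments(seg_b)
    if seg_a not in chain:
        raise StructuralError(
            f"{from_site!r} and {to_site!r} are not on one root-to-leaf path")
    if seg_a == seg_b and s_a > s_b:
        raise StructuralError(f"{to_site!r} is upstream of {from_site!r}")
    pieces: list[tuple[ArterialSegment, float]] = []  # (segment, length)
    for name in chain[chain.index(seg_a):]:
        seg = network.segments[name]
        lo = s_a if name == seg_a else 0.0
        hi = s_b if name == seg_b else 1.0
        if hi > lo:
            pieces.append((seg, (hi - lo) * seg.length))
        if name == seg_b:
            break
    total_l = sum(L for _, L in pieces)
    if total_l <= 0:
        raise StructuralError(
            f"zero path length between {from_site!r} and {to_site!r}")
    total_t = sum(L / theoretical_pwv(seg, rho) for seg, L in pieces)
    return total_l / total_t


# --------------------------------------------------------------------------
# foot detection and foot-to-foot PWV
# --------------------------------------------------------------------------

def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    # periodic extension: pulse waves are cyclic
    ext = np.concatenate([y[-w:], y, y[:w]])
    sm = np.convolve(ext, kernel, mode="same")
    return sm[w:-w]

def detect_foot(signal: np.ndarray, sampling_rate: float) -> FootDetection:
    """Intersecting-tangent foot of one cycle of a pulse wave.

    The tangent through the point of maximum upstroke slope (after a
    5-sample moving average) is intersected with the horizontal line
    through the preceding diastolic minimum, searched over the quarter
    cycle before the maximum-slope point (with periodic wrap).
    """
    y = np.asarray(signal, dtype=float)
    n = y.size
    if n < 10:
        raise DetectionError("signal too short for foot detection")
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise DetectionError("flat signal: no rising limb")
    raw_d = np.diff(y)
    if raw_d.max() - raw_d.min() <= 1e-9 * np.abs(raw_d).max():
        raise DetectionError("monotone signal: foot undefined")
    ys = _moving_average(y, 5)
    slopes = np.diff(ys) * sampling_rate
    # the systolic upstroke precedes the global peak: restrict the
    # max-slope search there so secondary features (e.g. the end-systolic
    # notch of flow waves) cannot capture it
    i_peak = int(np.argmax(ys))
    cand = slopes[:i_peak] if i_peak > 0 else slopes
    max_slope = float(cand.max())
    if max_slope <= 0:
        raise DetectionError("no rising systolic limb found")
    # first sample at the maximum slope (within float tolerance), so a
    # numerically flat upstroke resolves to its onset
    i_ms = int(np.argmax(cand >= max_slope * (1.0 - 1e-9)))
    # diastolic minimum in the quarter cycle preceding the max-slope point
    w = max(2, n // 4)
    idx = (np.arange(i_ms - w, i_ms) % n)
    y_min = float(ys[idx].min())
    t_ms = (i_ms + 0.5) / sampling_rate
    y_ms = 0.5 * (ys[i_ms] + ys[i_ms + 1])
    foot_time = t_ms - (y_ms - y_min) / max_slope
    return FootDetection(foot_time=foot_time, max_slope_time=t_ms,
                         diastolic_min=y_min)


def foot_to_foot_pwv(wave_prox: np.ndarray, wave_dist: np.ndarray,
                     delta_l: float, sampling_rate: float,
                     method: str = "foot_to_foot_pressure",
                     site_or_path: str = "",
                     theoretical: float = math.nan) -> PWVEstimate:
    """PWV = delta_L / delta_t between the feet of two same-cycle waves.

    ``delta_l`` is the difference of wave-travel path lengths from the
    inlet (heart) to the two measurement sites.
    """
    if delta_l <= 0:
        raise DomainError("path-length difference must be > 0")
    foot_p = detect_foot(wave_prox, sampling_rate)
    foot_d = detect_foot(wave_dist, sampling_rate)
    dt = foot_d.foot_time - foot_p.foot_time
    if dt <= 0:
        raise EstimationError(
            f"mis-ordered feet: distal foot ({foot_d.foot_time:.4f} s) does "
            f"not lag proximal foot ({foot_p.foot_time:.4f} s)")
    return PWVEstimate(method=method, site_or_path=site_or_path,
                       value=delta_l / dt, theoretical=theoretical,
                       meta={"delta_l": delta_l, "delta_t": dt,
                             "foot_prox": foot_p.foot_time,
                             "foot_dist": foot_d.foot_time})


# --------------------------------------------------------------------------
# loop estimators
# --------------------------------------------------------------------------

def _rsquared(x: np.ndarray, y: np.ndarray) -> float:
    sx = x - x.mean()
    sy = y - y.mean()
    denom = (sx ** 2).sum() * (sy ** 2).sum()
    if denom <= 0:
        return 1.0
    r = (sx * sy).sum() / math.sqrt(denom)
    return r * r


def _early_systolic_window(x: np.ndarray, y: np.ndarray, start: int,
                           cap: int, min_samples: int = 10,
                           r2_min: float = 0.99) -> slice:
    """Grow the fit window from ``start`` while the loop stays linear."""
    if cap - start < min_samples:
        raise EstimationError(
            f"early-systolic window shorter than {min_samples} samples")
    end = start + min_samples
    while end < cap:
        if _rsquared(x[start:end + 1], y[start:end + 1]) < r2_min:
            break
        end += 1
    return slice(start, end)


def _foot_index(series: np.ndarray, fs: float, n: int) -> tuple[int, float]:
    det = detect_foot(series, fs)
    idx = int(round(det.foot_time * fs))
    rng = series.max() - series.min()
    rise = np.diff(_moving_average(series, 5)).max() * fs / rng if rng > 0 else 0.0
    return max(0, min(idx, n - 1)), rise


def loop_pwv(variant: str, series1: np.ndarray, series2: np.ndarray,
             rho: float = BLOOD_DENSITY, sampling_rate: float = 1000.0,
             site_or_path: str = "",
             theoretical: float = math.nan) -> PWVEstimate:
    """Early-systolic loop PWV.

    ``variant`` is one of ``PU`` (series1=P, series2=U), ``QA``
    (series1=Q, series2=A) or ``lnDU`` (series1=D, series2=U). The linear
    window starts at the foot of the faster-rising series and grows
    sample-by-sample while the running linear fit keeps R^2 >= 0.99
    (minimum 10 samples), capped at the time of the peak derivative of
    the pressure/flow-like series (P, Q, or U respectively).
    """
    variant = variant.strip()
    if variant not in ("PU", "QA", "lnDU"):
        raise DomainError(f"unknown loop variant {variant!r}")
    if rho <= 0:
        raise DomainError("blood density must be > 0")
    s1 = np.asarray(series1, dtype=float)
    s2 = np.asarray(series2, dtype=float)
    if s1.shape != s2.shape:
        raise DomainError("loop series must have equal length")
    n = s1.size
    fs = sampling_rate

    i1, rise1 = _foot_index(s1, fs, n)
    i2, rise2 = _foot_index(s2, fs, n)
    start = i1 if rise1 >= rise2 else i2

    # cap: peak first derivative of the rapidly rising series, searched on
    # the upstroke (before that series' global peak)
    cap_series = s2 if variant == "lnDU" else s1
    smoothed = _moving_average(cap_series, 5)
    dcap = np.diff(smoothed)
    i_pk = int(np.argmax(smoothed))
    cap = int(np.argmax(dcap[:i_pk])) if i_pk > 0 else int(np.argmax(dcap))
    if cap <= start:
        cap = min(n - 1, start + int(0.08 * fs))  # fallback: 80 ms of systole

    if variant == "PU":
        x, y = s2, s1          # P vs U
    elif variant == "QA":
        x, y = s2, s1          # Q vs A
    else:
        if np.any(s1 <= 0):
            raise DomainError("diameters must be > 0 for the lnDU loop")
        x, y = np.log(s1), s2  # U vs lnD

    win = _early_systolic_window(x, y, start, cap)
    slope = float(np.polyfit(x[win], y[win], 1)[0])

    if variant == "PU":
        value = slope / rho
    elif variant == "QA":
        value = slope
    else:
        value = 0.5 * slope
    if value <= 0:
        raise EstimationError(
            f"{variant}-loop slope non-positive (reflection-dominated site)")
    return PWVEstimate(method=f"{variant}_loop", site_or_path=site_or_path,
                       value=value, theoretical=theoretical,
                       meta={"window_start": win.start, "window_stop": win.stop})


def sum_of_squares_pwv(P: np.ndarray, U: np.ndarray,
                       rho: float = BLOOD_DENSITY,
                       sampling_rate: float = 1000.0,
                       site_or_path: str = "",
                       theoretical: float = math.nan) -> PWVEstimate:
    """Single-site PWV from summed squared increments over one cycle."""
    if rho <= 0:
        raise DomainError("blood density must be > 0")
    P = np.asarray(P, dtype=float)
    U = np.asarray(U, dtype=float)
    if P.shape != U.shape:
        raise DomainError("P and U must have equal length")
    dP = np.diff(P)
    dU = np.diff(U)
    sdU2 = float((dU ** 2).sum())
    if sdU2 <= 0:
        raise EstimationError("constant velocity: sum-of-squares undefined")
    value = math.sqrt(float((dP ** 2).sum()) / sdU2) / rho
    return PWVEstimate(method="sum_of_squares", site_or_path=site_or_path,
                       value=value, theoretical=theoretical)


# --------------------------------------------------------------------------
# reflection coefficients
# --------------------------------------------------------------------------

def reflection_coefficient(Ap: float, cp: float, Ad1: float, cd1: float,
                           Ad2: float, cd2: float,
                           rho: float = BLOOD_DENSITY,
                           bifurcation: tuple[str, str, str] =
                           ("parent", "d1", "d2")) -> ReflectionResult:
    """Admittance-mismatch reflection coefficient of a bifurcation."""
    for v in (Ap, cp, Ad1, cd1, Ad2, cd2, rho):
        if v <= 0:
            raise DomainError("areas, speeds and density must be > 0")
    Yp = Ap / (rho * cp)
    Yd1 = Ad1 / (rho * cd1)
    Yd2 = Ad2 / (rho * cd2)
    Rt = (Yp - Yd1 - Yd2) / (Yp + Yd1 + Yd2)
    return ReflectionResult(bifurcation=bifurcation, Yp=Yp, Yd1=Yd1, Yd2=Yd2,
                            Rt=Rt)


def mean_reflection_coefficient(network: ArterialNetwork,
                                rho: float = BLOOD_DENSITY) -> float:
    """Arithmetic mean of Rt over all bifurcations of the network.

    Parent admittance is evaluated at the parent's distal end, daughter
    admittances at their proximal ends, with the theoretical wave speed
    at those positions.
    """
    if not network.bifurcations:
        raise DomainError("network has no bifurcations")
    total = 0.0
    for p, d1, d2 in network.bifurcations:
        sp = network.segments[p]
        s1 = network.segments[d1]
        s2 = network.segments[d2]
        res = reflection_coefficient(
            sp.area_at(1.0), segment_wave_speed(sp, rho, s=1.0),
            s1.area_at(0.0), segment_wave_speed(s1, rho, s=0.0),
            s2.area_at(0.0), segment_wave_speed(s2, rho, s=0.0),
            rho, bifurcation=(p, d1, d2))
        total += res.Rt
    return total / len(network.bifurcations)
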