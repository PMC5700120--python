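"""Central aortic pressure reconstruction from non-invasive inputs.

The target aortic pressure wave is assembled from three pieces:

1. an early systolic upstroke given by the water-hammer relation,
   P(t) = DBP + rho * PWV * U(t), from the foot of the aortic velocity
   wave U to the time of peak U — making the systolic shoulder
   P1 = DBP + rho * PWV * max(U);
2. a late systolic second-order polynomial, continuous in value and
   slope at the junction, whose remaining coefficient is fixed by
   conservation of the mean arterial pressure over the full cycle;
3. a diastolic exponential decay with the time constant tau measured on
   a peripheral (brachial) pressure wave, decaying toward zero absolute
   pressure from the end-systolic value.

If the decay misses DBP at cycle end by more than 1 mmHg, tau is
rescaled to close the cycle (a warning is logged) and the polynomial
re-solved, keeping MAP conservation exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._defaults import BLOOD_DENSITY, MMHG
from .errors import DomainError, EstimationError, ReconstructionError
from .pwv_estimators import detect_foot
from .wave_analysis import detect_shoulder

__all__ = [
    "CBPInputs",
    "ReconstructedPressure",
    "P1Result",
    "fit_diastolic_decay",
    "brachial_calibration",
    "reconstruct_central_pressure",
    "p1_error",
]

logger = logging.getLogger(__name__)


@dataclass
class CBPInputs:
    """Inputs of the central-pressure algorithm (SI units)."""

    U: np.ndarray            # aortic velocity over one cycle [m/s]
    pwv_value: float         # aortic stiffness estimate [m/s]
    MAP: float               # mean arterial pressure [Pa]
    DBP: float               # diastolic pressure [Pa]
    tau: float               # diastolic decay constant [s]
    sampling_rate: float = 1000.0
    rho: float = BLOOD_DENSITY

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.DBP >= self.MAP:
            raise DomainError("DBP must be below MAP")
        if self.tau <= 0:
            raise DomainError("diastolic decay constant must be > 0")
        if self.pwv_value <= 0:
            raise DomainError("PWV input must be > 0")
        if self.U.size < 20:
            raise DomainError("velocity wave too short")

    @property
    def period(self) -> float:
        return self.U.size / self.sampling_rate


@dataclass
class ReconstructedPressure:
    """Output wave with its piecewise structure."""

    P: np.ndarray            # Pa, one cycle
    P1: float                # Pa, systolic shoulder (water-hammer at peak U)
    t_peak_u: float          # s, end of water-hammer limb
    t_end_systole: float     # s, end of polynomial limb
    labels: np.ndarray = field(repr=False, default=None)  # per-sample piece
    tau_used: float = math.nan
    tau_rescaled: bool = False
    sampling_rate: float = 1000.0


@dataclass(frozen=True)
class P1Result:
    P1_algo: float   # Pa
    P1_ref: float    # Pa
    epsilon: float   # Pa (P1_algo - P1_ref)

    @property
    def epsilon_mmhg(self) -> float:
        return self.epsilon / MMHG


def fit_diastolic_decay(peripheral_P: np.ndarray,
                        sampling_rate: float) -> float:
    """Diastolic decay constant tau from a peripheral pressure wave.

    Diastole is taken from the systolic peak to cycle end; tau is the
    least-squares exponential (zero-asymptote) fit over its final two
    thirds. Raises :class:`EstimationError` for a non-decaying diastole.
    """
    P = np.asarray(peripheral_P, dtype=float)
    n = P.size
    if n < 20:
        raise DomainError("pressure wave too short")
    if np.any(P <= 0):
        raise DomainError("absolute pressures must be positive for the fit")
    i_peak = int(np.argmax(P))
    n_dia = n - i_peak
    if n_dia < 10:
        raise EstimationError("no diastolic limb after the systolic peak")
    start = i_peak + n_dia // 3
    seg = P[start:]
    if seg[-1] >= seg[0] - 1e-12:
        raise EstimationError("diastole does not decay: cannot fit tau")
    t = np.arange(seg.size) / sampling_rate
    slope = np.polyfit(t, np.log(seg), 1)[0]
    if slope >= 0:
        raise EstimationError("diastolic pressure not exponentially decaying")
    return -1.0 / slope


def brachial_calibration(peripheral_P: np.ndarray) -> tuple[float, float]:
    """(MAP, DBP) from a peripheral pressure wave: time mean and minimum."""
    P = np.asarray(peripheral_P, dtype=float)
    return float(P.mean()), float(P.min())


def reconstruct_central_pressure(inputs: CBPInputs) -> ReconstructedPressure:
    """Assemble the three-piece central pressure wave from the inputs."""
    U = inputs.U
    fs = inputs.sampling_rate
    n = U.size
    rho_c = inputs.rho * inputs.pwv_value

    foot = detect_foot(U, fs)
    i_foot = max(0, int(round(foot.foot_time * fs)))
    i_pk = int(np.argmax(U))
    if i_pk <= i_foot:
        raise ReconstructionError("velocity peak precedes its own foot")
    u_max = float(U[i_pk])

    # end of systole: forward velocity falls below 5% of its peak
    below = np.where(U[i_pk:] < 0.05 * u_max)[0]
    i_es = i_pk + int(below[0]) if below.size else i_pk + int(np.argmin(U[i_pk:]))
    i_es = min(i_es, n - 2)

    p1 = inputs.DBP + rho_c * u_max
    t = np.arange(n) / fs
    t1 = i_pk / fs
    t_es = i_es / fs

    # upstroke slope at the junction (water-hammer limb derivative)
    du = np.gradient(U, 1.0 / fs)
    m = rho_c * float(du[i_pk])

    k_quad = np.arange(i_pk, i_es + 1)
    tq = (k_quad - i_pk) / fs
    k_dec = np.arange(i_es + 1, n)

    tau = inputs.tau
    rescaled = False
    a = 0.0
    for _ in range(25):
        e_dec = np.exp(-((k_dec - i_es) / fs) / tau)
        # full-cycle mean linear in the free quadratic coefficient a:
        # sum(P) = S0 + a * Sa  with  P_es = p1 + m*(t_es-t1) + a*(t_es-t1)^2
        d_es = t_es - t1
        s0 = (inputs.DBP * i_foot
              + float((inputs.DBP + rho_c * U[i_foot:i_pk]).sum())
              + float((p1 + m * tq).sum())
              + (p1 + m * d_es) * float(e_dec.sum()))
        sa = float((tq ** 2).sum()) + d_es ** 2 * float(e_dec.sum())
        if sa <= 0:
            raise ReconstructionError(
                "degenerate late-systolic window: cannot conserve MAP",
                map_residual_mmhg=(inputs.MAP * n - s0) / n / MMHG)
        a = (inputs.MAP * n - s0) / sa
        p_es = p1 + m * d_es + a * d_es ** 2
        if p_es <= inputs.DBP:
            raise ReconstructionError(
                "end-systolic pressure at or below DBP: MAP inconsistent "
                "with DBP and the velocity wave",
                map_residual_mmhg=(p_es - inputs.DBP) / MMHG)
        p_end = p_es * math.exp(-((n - 1 - i_es) / fs) / tau)
        if abs(p_end - inputs.DBP) <= 1.0 * MMHG:
            break
        # rescale tau so the decay lands on DBP at cycle end
        tau = ((n - 1 - i_es) / fs) / math.log(p_es / inputs.DBP)
        rescaled = True
    if rescaled:
        logger.warning(
            "diastolic tau rescaled from %.3f to %.3f s to close the cycle",
            inputs.tau, tau)

    P = np.empty(n)
    labels = np.empty(n, dtype=object)
    P[:i_foot] = inputs.DBP
    labels[:i_foot] = "upstroke"
    P[i_foot:i_pk] = inputs.DBP + rho_c * U[i_foot:i_pk]
    labels[i_foot:i_pk] = "upstroke"
    P[k_quad] = p1 + m * tq + a * tq ** 2
    labels[k_quad] = "polynomial"
    P[k_dec] = p_es * np.exp(-((k_dec - i_es) / fs) / tau)
    labels[k_dec] = "decay"

    if P.min() < inputs.DBP - 0.05 * MMHG:
        raise ReconstructionError(
            "reconstructed wave dips below DBP: MAP inconsistent with inputs",
            map_residual_mmhg=(P.min() - inputs.DBP) / MMHG)

    return ReconstructedPressure(P=P, P1=p1, t_peak_u=t1, t_end_systole=t_es,
                                 labels=labels, tau_used=tau,
                                 tau_rescaled=rescaled, sampling_rate=fs)


def p1_error(reconstructed: ReconstructedPressure,
             reference_P: np.ndarray,
             sampling_rate: float = 1000.0) -> P1Result:
    """Shoulder-pressure error against the reference aortic wave."""
    _, p1_ref = detect_shoulder(reference_P, sampling_rate)
    eps = reconstructed.P1 - p1_ref
    return P1Result(P1_algo=reconstructed.P1, P1_ref=p1_ref, epsilon=eps)
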