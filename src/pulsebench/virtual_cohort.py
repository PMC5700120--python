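"""Virtual-subject generation: reduced arterial network, cohort sampling,
and the 1D pulse-propagation simulation to periodic steady state.

A *virtual subject* is one sampled set of cardiac and arterial parameters
together with the converged periodic pressure/flow/area waveforms it
produces at the named measurement sites of a branching elastic-tube
network. The network is a documented 17-segment reduction of the adult
systemic tree (see :mod:`pulsebench._defaults`): aorta, carotid with its
internal/external bifurcation, one (paired-lumped) subclavian-brachial
arm, both iliacs and one leg to the ankle, each leaf terminated by an
RCR Windkessel.

Units are SI throughout this module; file I/O converts to the clinical
units (mmHg, mL/s, cm^2) documented in :mod:`pulsebench.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from . import _solver
from ._defaults import BLOOD_DENSITY, MMHG, default_config
from .config import NumericsConfig, validate_ranges
from .errors import (
    ConvergenceError,
    DomainError,
    StabilityError,
    StructuralError,
)

__all__ = [
    "ArterialSegment",
    "WindkesselOutlet",
    "ArterialNetwork",
    "InflowWaveform",
    "SubjectParameters",
    "WaveformSet",
    "SubjectRecord",
    "build_reduced_network",
    "sample_cohort",
    "scale_network",
    "make_inflow",
    "simulate_subject",
    "segment_wave_speed",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArterialSegment:
    """A tapered thin-walled elastic tube.

    Radii are lumen radii at the reference pressure (the tube-law offset
    ``p_ref``); taper is linear in radius between the two ends.
    """

    name: str
    length: float          # m
    radius_prox: float     # m
    radius_dist: float     # m
    wall_thickness: float  # m
    youngs_modulus: float  # Pa
    wall_class: str = "elastic"  # {elastic | muscular}

    def __post_init__(self):
        if self.length <= 0:
            raise DomainError(f"segment {self.name!r}: length must be > 0")
        if self.radius_prox <= 0 or self.radius_dist <= 0:
            raise DomainError(f"segment {self.name!r}: radii must be > 0")
        if self.wall_thickness <= 0 or self.youngs_modulus <= 0:
            raise DomainError(
                f"segment {self.name!r}: wall thickness and Young's modulus "
                "must be > 0")
        if self.wall_class not in ("elastic", "muscular"):
            raise DomainError(
                f"segment {self.name!r}: wall_class must be elastic|muscular")

    @property
    def beta(self) -> float:
        """Tube-law stiffness beta = (4/3) sqrt(pi) E h  [Pa m]."""
        return (4.0 / 3.0) * math.sqrt(math.pi) * self.youngs_modulus \
            * self.wall_thickness

    def radius_at(self, s: float) -> float:
        """Lumen radius at relative position s in [0, 1]."""
        return self.radius_prox + (self.radius_dist - self.radius_prox) * s

    def area_at(self, s: float) -> float:
        r = self.radius_at(s)
        return math.pi * r * r


def segment_wave_speed(segment: ArterialSegment, rho: float = BLOOD_DENSITY,
                       s: float = 0.5) -> float:
    """Theoretical (Moens-Korteweg) wave speed at relative position ``s``.

    c = sqrt(beta / (2 rho sqrt(A_d))), the tube-law slope speed at the
    reference area, which for an incompressible thin wall equals
    sqrt((4/3) E h / (rho D)).
    """
    if rho <= 0:
        raise DomainError("blood density must be > 0")
    Ad = segment.area_at(s)
    return math.sqrt(segment.beta / (2.0 * rho * math.sqrt(Ad)))


@dataclass(frozen=True)
class WindkesselOutlet:
    """RCR terminal: proximal resistance, compliance, distal resistance."""

    proximal_resistance: float  # Pa s / m^3
    compliance: float           # m^3 / Pa
    distal_resistance: float    # Pa s / m^3
    outflow_pressure: float     # Pa

    def __post_init__(self):
        if (self.proximal_resistance <= 0 or self.compliance <= 0
                or self.distal_resistance <= 0):
            raise DomainError("Windkessel resistances and compliance must be > 0")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance


@dataclass
class ArterialNetwork:
    """Tree of arterial segments rooted at the inflow segment.

    ``bifurcations`` lists (parent, daughter1, daughter2) branch points;
    ``conjunctions`` lists (parent, daughter) in-line joints where one
    named segment simply continues into the next. ``sites`` maps a
    measurement-site label to (segment name, relative position in [0,1]).
    """

    segments: dict[str, ArterialSegment]
    bifurcations: list[tuple[str, str, str]]
    conjunctions: list[tuple[str, str]]
    inlet: str
    outlets: dict[str, WindkesselOutlet]
    sites: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._validate()

    # -- topology ----------------------------------------------------------
    def children(self, name: str) -> list[str]:
        out = []
        for p, d1, d2 in self.bifurcations:
            if p == name:
                out += [d1, d2]
        for p, d in self.conjunctions:
            if p == name:
                out.append(d)
        return out

    @property
    def parent_map(self) -> dict[str, str]:
        pm: dict[str, str] = {}
        for p, d1, d2 in self.bifurcations:
            pm[d1] = p
            pm[d2] = p
        for p, d in self.conjunctions:
            pm[d] = p
        return pm

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.segments if not self.children(n)]

    def _validate(self):
        pm: dict[str, str] = {}
        for p, d1, d2 in self.bifurcations:
            if d1 == d2:
                raise StructuralError(
                    f"bifurcation of {p!r} lists daughter {d1!r} twice")
            for d in (d1, d2):
                if d in pm:
                    raise StructuralError(
                        f"segment {d!r} has more than one parent")
                pm[d] = p
        for p, d in self.conjunctions:
            if d in pm:
                raise StructuralError(f"segment {d!r} has more than one parent")
            pm[d] = p
        names = set(self.segments)
        for d, p in pm.items():
            if d not in names:
                raise StructuralError(f"unknown daughter segment {d!r}")
            if p not in names:
                raise StructuralError(f"unknown parent segment {p!r}")
        if self.inlet not in names:
            raise StructuralError(f"inlet segment {self.inlet!r} not defined")
        if self.inlet in pm:
            raise StructuralError("inlet segment must not have a parent")
        # reachability from the root (detects cycles and orphans)
        seen = set()
        stack = [self.inlet]
        while stack:
            n = stack.pop()
            if n in seen:
                raise StructuralError(f"cycle detected at segment {n!r}")
            seen.add(n)
            stack.extend(self.children(n))
        orphans = names - seen
        if orphans:
            raise StructuralError(
                f"segments not connected to the inlet: {sorted(orphans)}")
        for leaf in self.leaves:
            if leaf not in self.outlets:
                raise StructuralError(f"leaf segment {leaf!r} has no outlet")
        for name in self.outlets:
            if name not in names:
                raise StructuralError(f"outlet on unknown segment {name!r}")
        for site, (seg, s) in self.sites.items():
            if seg not in names:
                raise StructuralError(f"site {site!r} on unknown segment {seg!r}")
            if not 0.0 <= s <= 1.0:
                raise StructuralError(f"site {site!r}: position {s} outside [0,1]")

    # -- geometry ----------------------------------------------------------
    def path_segments(self, name: str) -> list[str]:
        """Segments from the inlet to ``name``, inclusive."""
        pm = self.parent_map
        chain = [name]
        while chain[-1] != self.inlet:
            chain.append(pm[chain[-1]])
        return chain[::-1]

    def path_length_to(self, segment: str, s: float = 1.0) -> float:
        """Wave-travel distance from the inlet to position s of ``segment``."""
        chain = self.path_segments(segment)
        length = sum(self.segments[n].length for n in chain[:-1])
        return length + s * self.segments[segment].length

    @property
    def path_lengths(self) -> dict[str, float]:
        """Wave-travel distance from the inlet to every named site [m]."""
        return {site: self.path_length_to(seg, s)
                for site, (seg, s) in self.sites.items()}

    def site_local(self, site: str) -> tuple[str, float]:
        if site not in self.sites:
            raise StructuralError(f"unknown site {site!r}")
        return self.sites[site]

    def total_peripheral_resistance(self) -> float:
        """Parallel combination of all terminal RCR total resistances."""
        return 1.0 / sum(1.0 / wk.total_resistance
                         for wk in self.outlets.values())


@dataclass
class InflowWaveform:
    """Aortic-root flow over one period: skewed sinusoidal systolic
    ejection (fast quarter-sine rise, slower quarter-cosine decay, as in
    measured aortic outflow) with a brief end-systolic backflow notch and
    zero flow in diastole."""

    period: float         # s
    ejection_time: float  # s (forward-ejection duration)
    stroke_volume: float  # m^3 (net volume per beat)
    backflow_fraction: float = 0.02
    backflow_duration: float = 0.06
    rise_fraction: float = 0.3  # fraction of ejection time to peak flow

    _Q_SHAPE_FACTOR = 2.0  # Qmax = factor * V_forward / ejection_time

    def __post_init__(self):
        if self.ejection_time + self.backflow_duration >= self.period:
            raise DomainError("ejection (plus notch) must end before the period")
        if self.stroke_volume < 0:
            raise DomainError("stroke volume must be >= 0")
        if not 0.05 <= self.rise_fraction <= 0.95:
            raise DomainError("rise_fraction must lie in [0.05, 0.95]")

    def flow_at(self, t):
        """Flow rate [m^3/s] at time(s) t (periodic)."""
        t = np.asarray(t, dtype=float) % self.period
        te, tb = self.ejection_time, self.backflow_duration
        tr = self.rise_fraction * te
        vf = self.stroke_volume / (1.0 - self.backflow_fraction)
        # smoothstep (half-cosine) rise and fall: C1 at onset, peak and
        # end of ejection; both halves integrate to Qmax * duration / 2,
        # so the peak flow is independent of the skew
        qmax = self._Q_SHAPE_FACTOR * vf / te
        q = np.zeros_like(t)
        rise = t <= tr
        fall = (t > tr) & (t <= te)
        q[rise] = qmax * 0.5 * (1.0 - np.cos(np.pi * t[rise] / max(tr, 1e-12)))
        q[fall] = qmax * 0.5 * (1.0 + np.cos(np.pi * (t[fall] - tr)
                                             / max(te - tr, 1e-12)))
        if tb > 0 and self.backflow_fraction > 0:
            vb = self.backflow_fraction * vf
            qb = math.pi * vb / (2.0 * tb)
            notch = (t > te) & (t <= te + tb)
            q[notch] = -qb * np.sin(np.pi * (t[notch] - te) / tb)
        return q

    def samples(self, sampling_rate: float = 1000.0):
        """(time, flow) arrays over one period."""
        n = int(round(self.period * sampling_rate))
        t = np.arange(n) / sampling_rate
        return t, self.flow_at(t)


@dataclass(frozen=True)
class SubjectParameters:
    """One sampled virtual subject (cardiac + arterial scaling factors)."""

    heart_rate: float               # bpm
    stroke_volume: float            # mL
    ejection_time: float            # s
    c_el_factor: float              # scales E*h of elastic segments
    muscular_stiffness_scale: float
    diameter_scale: float
    peripheral_resistance_scale: float
    peripheral_compliance_scale: float
    blood_density: float = BLOOD_DENSITY  # kg/m^3
    seed: int = 0

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class WaveformSet:
    """Per-site periodic time series over one cardiac cycle (SI units)."""

    sites: list[str]
    sampling_rate: float  # Hz
    period: float         # s
    data: dict[str, dict[str, np.ndarray]]  # site -> {P, Q, A}

    @property
    def n_samples(self) -> int:
        return int(round(self.period * self.sampling_rate))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def pressure(self, site: str) -> np.ndarray:
        return self.data[site]["P"]

    def flow(self, site: str) -> np.ndarray:
        return self.data[site]["Q"]

    def area(self, site: str) -> np.ndarray:
        return self.data[site]["A"]

    def velocity(self, site: str) -> np.ndarray:
        return self.data[site]["Q"] / self.data[site]["A"]

    def diameter(self, site: str) -> np.ndarray:
        return 2.0 * np.sqrt(self.data[site]["A"] / np.pi)


@dataclass
class SubjectRecord:
    """A virtual subject: parameters, scaled network, waveforms, and the
    exact theoretical wave speed of every segment and site."""

    parameters: SubjectParameters
    network: ArterialNetwork
    waveforms: WaveformSet
    theoretical_pwv: dict[str, float]
    subject_id: str = "subject"


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

def build_reduced_network(config: dict | None = None) -> ArterialNetwork:
    """Build the arterial tree from a ``network`` config block.

    With ``config=None`` the built-in 15-segment reduced systemic tree is
    returned. The Windkessel of each leaf is derived from the configured
    systemic totals: R_i = R_total / flow_fraction_i, with the proximal
    resistance set to the terminal characteristic impedance capped at
    ``r1_cap_fraction * R_i``, and C_i = C_total * flow_fraction_i.
    """
    if config is None:
        config = default_config()["network"]
    elif "network" in config:
        config = config["network"]

    segs = {}
    for name, spec in config["segments"].items():
        if isinstance(spec, dict):
            segs[name] = ArterialSegment(name=name, **spec)
        else:
            L, rp, rd, h, E, wc = spec
            segs[name] = ArterialSegment(name, L, rp, rd, h, E, wc)

    bifs: list[tuple[str, str, str]] = []
    conjs: list[tuple[str, str]] = []
    for parent, daughters in config["children"].items():
        if len(daughters) == 2:
            bifs.append((parent, daughters[0], daughters[1]))
        elif len(daughters) == 1:
            conjs.append((parent, daughters[0]))
        else:
            raise StructuralError(
                f"segment {parent!r} lists {len(daughters)} daughters; "
                "only 1 or 2 are supported")

    inlet = config["inlet"]
    sites = {k: (v[0], float(v[1])) for k, v in config.get("sites", {}).items()}

    leaves = sorted(set(segs) - set(config["children"].keys()))

    outlets: dict[str, WindkesselOutlet] = {}
    if "outlets" in config:
        for name, wk in config["outlets"].items():
            outlets[name] = WindkesselOutlet(**wk)
    else:
        wkcfg = config["windkessel"]
        r_tot = float(wkcfg["total_resistance"])
        c_tot = float(wkcfg["total_compliance"])
        pout = float(wkcfg["outflow_pressure_mmhg"]) * MMHG
        cap = float(wkcfg.get("r1_cap_fraction", 0.4))
        fracs = wkcfg["flow_fractions"]
        missing = [leaf for leaf in leaves if leaf not in fracs]
        if missing:
            raise StructuralError(
                f"no Windkessel flow fraction for leaf segment(s) {missing}")
        for leaf in leaves:
            f = float(fracs[leaf])
            seg = segs[leaf]
            r_i = r_tot / f
            z_term = BLOOD_DENSITY * segment_wave_speed(seg, s=1.0) \
                / seg.area_at(1.0)
            r1 = min(z_term, cap * r_i)
            outlets[leaf] = WindkesselOutlet(
                proximal_resistance=r1,
                compliance=c_tot * f,
                distal_resistance=r_i - r1,
                outflow_pressure=pout,
            )

    return ArterialNetwork(segments=segs, bifurcations=bifs,
                           conjunctions=conjs, inlet=inlet,
                           outlets=outlets, sites=sites)


def scale_network(network: ArterialNetwork,
                  params: SubjectParameters) -> ArterialNetwork:
    """Apply a subject's scaling factors to a baseline network.

    Elastic/muscular stiffness factors multiply E (hence E*h and the tube
    stiffness beta); the diameter scale multiplies all radii; peripheral
    scales multiply the Windkessel resistances and compliances.
    """
    segs = {}
    for name, seg in network.segments.items():
        stiff = (params.c_el_factor if seg.wall_class == "elastic"
                 else params.muscular_stiffness_scale)
        segs[name] = replace(
            seg,
            radius_prox=seg.radius_prox * params.diameter_scale,
            radius_dist=seg.radius_dist * params.diameter_scale,
            youngs_modulus=seg.youngs_modulus * stiff,
        )
    outlets = {}
    for name, wk in network.outlets.items():
        outlets[name] = WindkesselOutlet(
            proximal_resistance=wk.proximal_resistance
            * params.peripheral_resistance_scale,
            compliance=wk.compliance * params.peripheral_compliance_scale,
            distal_resistance=wk.distal_resistance
            * params.peripheral_resistance_scale,
            outflow_pressure=wk.outflow_pressure,
        )
    return ArterialNetwork(segments=segs, bifurcations=list(network.bifurcations),
                           conjunctions=list(network.conjunctions),
                           inlet=network.inlet, outlets=outlets,
                           sites=dict(network.sites))


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

_PARAM_ORDER = (
    "heart_rate",
    "stroke_volume",
    "ejection_time",
    "c_el_factor",
    "muscular_stiffness_scale",
    "diameter_scale",
    "peripheral_resistance_scale",
    "peripheral_compliance_scale",
)


def sample_cohort(ranges: dict, n: int, seed: int) -> list[SubjectParameters]:
    """Latin-hypercube sample of ``n`` subjects within the healthy ranges.

    Deterministic given ``seed``. Degenerate ranges (lower == upper) pin
    that parameter for the whole cohort.
    """
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    rng = validate_ranges(ranges)
    sampler = qmc.LatinHypercube(d=len(_PARAM_ORDER), seed=seed)
    unit = sampler.random(n)
    subjects = []
    for i in range(n):
        vals = {}
        for j, key in enumerate(_PARAM_ORDER):
            lo, hi = rng[key]
            vals[key] = lo + unit[i, j] * (hi - lo)
        subjects.append(SubjectParameters(seed=seed + i, **vals))
    return subjects


def make_inflow(params: SubjectParameters,
                numerics: NumericsConfig) -> InflowWaveform:
    """Aortic-root inflow for one subject."""
    return InflowWaveform(
        period=params.period,
        ejection_time=params.ejection_time,
        stroke_volume=params.stroke_volume * 1e-6,
        backflow_fraction=numerics.backflow_fraction,
        backflow_duration=numerics.backflow_duration,
        rise_fraction=numerics.ejection_rise_fraction,
    )


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _as_numerics(numerics) -> NumericsConfig:
    if numerics is None:
        return NumericsConfig()
    if isinstance(numerics, NumericsConfig):
        return numerics
    return NumericsConfig(**numerics)


def simulate_subject(params: SubjectParameters,
                     network: ArterialNetwork,
                     numerics: NumericsConfig | dict | None = None,
                     extra_probes: dict[str, tuple[str, float]] | None = None,
                     subject_id: str = "subject") -> SubjectRecord:
    """Solve the 1D equations on the scaled network to a periodic state.

    The baseline ``network`` is scaled by the subject's factors, the
    aortic-root inflow prescribed, and cycles run until the maximum
    cycle-to-cycle pressure change at every site drops below the
    periodicity tolerance. ``extra_probes`` adds recording points (same
    format as sites) without making them part of the site list.

    Raises :class:`ConvergenceError` if the cycle budget is exhausted and
    :class:`StabilityError` on numerical blow-up (negative area).
    """
    num = _as_numerics(numerics)
    net = scale_network(network, params)
    rho = params.blood_density
    inflow = make_inflow(params, num)
    p_ref = num.p_ref_mmhg * MMHG

    names = list(net.segments)
    seg_index = {n: i for i, n in enumerate(names)}
    nseg = len(names)
    seg_n = np.empty(nseg, dtype=np.int64)
    seg_dx = np.empty(nseg)
    for i, n in enumerate(names):
        L = net.segments[n].length
        nn = max(4, int(round(L / num.dx)) + 1)
        seg_n[i] = nn
        seg_dx[i] = L / (nn - 1)
    seg_start = np.zeros(nseg, dtype=np.int64)
    seg_start[1:] = np.cumsum(seg_n)[:-1]
    N = int(seg_n.sum())

    b = np.empty(N)
    Ad = np.empty(N)
    for i, n in enumerate(names):
        seg = net.segments[n]
        s = np.linspace(0.0, 1.0, seg_n[i])
        r = seg.radius_prox + (seg.radius_dist - seg.radius_prox) * s
        a = np.pi * r * r
        sl = slice(seg_start[i], seg_start[i] + seg_n[i])
        Ad[sl] = a
        b[sl] = seg.beta / a
    sqAd = np.sqrt(Ad)

    junctions = [(p, d1, d2) for p, d1, d2 in net.bifurcations]
    junctions += [(p, d, None) for p, d in net.conjunctions]
    jp = np.array([seg_index[j[0]] for j in junctions], dtype=np.int64)
    jd1 = np.array([seg_index[j[1]] for j in junctions], dtype=np.int64)
    jd2 = np.array([seg_index[j[2]] if j[2] is not None else -1
                    for j in junctions], dtype=np.int64)
    if len(junctions) == 0:
        jp = np.empty(0, dtype=np.int64)
        jd1 = np.empty(0, dtype=np.int64)
        jd2 = np.empty(0, dtype=np.int64)

    out_names = sorted(net.outlets)
    out_seg = np.array([seg_index[n] for n in out_names], dtype=np.int64)
    oR1 = np.array([net.outlets[n].proximal_resistance for n in out_names])
    oR2 = np.array([net.outlets[n].distal_resistance for n in out_names])
    oC = np.array([net.outlets[n].compliance for n in out_names])
    # the kernel works in gauge pressure (relative to the tube-law offset
    # p_ref), so the Windkessel pressures are shifted accordingly
    oPout = np.array([net.outlets[n].outflow_pressure for n in out_names]) - p_ref

    # recording nodes: named sites plus any extra probes
    rec_map = dict(net.sites)
    if extra_probes:
        for k, v in extra_probes.items():
            rec_map[k] = (v[0], float(v[1]))
    rec_names = list(rec_map)
    rec_nodes = np.empty(len(rec_names), dtype=np.int64)
    for k, name in enumerate(rec_names):
        segname, s = rec_map[name]
        i = seg_index[segname]
        rec_nodes[k] = seg_start[i] + int(round(s * (seg_n[i] - 1)))

    # CFL time step from the stiffest node with margin for distension
    c_ref = np.sqrt(0.5 * b * sqAd / rho)
    c_max = float(c_ref.max()) * 1.35 + 3.0
    dt = num.cfl * float(seg_dx.min()) / c_max
    nsteps = int(math.ceil(inflow.period / dt))
    dt = inflow.period / nsteps
    qin = inflow.flow_at(dt * (np.arange(nsteps) + 1.0))

    # initial state: uniform pressure at the estimated mean
    q_mean = inflow.stroke_volume / inflow.period
    r_total = net.total_peripheral_resistance()
    p_init = float(oPout.mean()) + q_mean * r_total
    A = (sqAd + (p_init - p_ref) / b) ** 2
    U = np.zeros(N)
    # compliance pressures (gauge) start at the estimated mean: cuts the
    # number of cycles needed to fill/drain the Windkessels to periodicity
    Pc = np.full(len(out_names), max(p_init - p_ref, float(oPout.max())))

    fric = 2.0 * (num.profile_zeta + 2.0) * math.pi * num.blood_viscosity
    recP = np.empty((nsteps, len(rec_names)))
    recQ = np.empty((nsteps, len(rec_names)))
    recA = np.empty((nsteps, len(rec_names)))
    prevP = None
    residual = math.inf
    converged = False
    for cycle in range(num.max_cycles):
        status = _solver.run_cycle(
            A, U, Pc, dt, qin, b, sqAd, seg_start, seg_n, seg_dx,
            jp, jd1, jd2, out_seg, oR1, oR2, oC, oPout,
            seg_index[net.inlet], rho, fric, rec_nodes, recP, recQ, recA)
        if status != 0:
            raise StabilityError(
                f"negative area in cycle {cycle + 1}; "
                "reduce the time step (smaller dx or CFL)")
        if prevP is not None:
            residual = float(np.abs(recP - prevP).max()) / MMHG
            if residual < num.periodicity_tol_mmhg and cycle + 1 >= num.min_cycles:
                converged = True
                break
        prevP = recP.copy()
    if not converged:
        raise ConvergenceError(
            f"no periodic state after {num.max_cycles} cycles "
            f"(residual {residual:.3f} mmHg)", residual_mmhg=residual)

    # resample the converged cycle to the output rate
    n_out = int(round(inflow.period * num.output_rate))
    t_out = np.arange(n_out) / num.output_rate
    t_sol = np.concatenate(([0.0], dt * (np.arange(nsteps) + 1.0)))
    data: dict[str, dict[str, np.ndarray]] = {}
    for k, name in enumerate(rec_names):
        series = {}
        for key, rec in (("P", recP), ("Q", recQ), ("A", recA)):
            y = np.concatenate(([rec[-1, k]], rec[:, k]))
            series[key] = np.interp(t_out, t_sol, y)
        series["P"] = series["P"] + p_ref
        data[name] = series

    waveforms = WaveformSet(sites=rec_names, sampling_rate=num.output_rate,
                            period=inflow.period, data=data)

    theo: dict[str, float] = {}
    for n in names:
        theo[n] = segment_wave_speed(net.segments[n], rho)
    for site, (segname, _s) in rec_map.items():
        theo[site] = segment_wave_speed(net.segments[segname], rho)

    return SubjectRecord(parameters=params, network=net, waveforms=waveforms,
                         theoretical_pwv=theo, subject_id=subject_id)


def generate_cohort(config: dict | None = None,
                    n: int | None = None,
                    seed: int | None = None,
                    progress: bool = False,
                    ) -> tuple[list[SubjectRecord], list[dict]]:
    """Sample and simulate a whole cohort.

    Returns (records, failures); a failed subject (non-convergent or
    unstable) is logged and excluded, never aborts the cohort.
    """
    from .config import load_config  # local import to avoid cycle at import

    cfg = load_config() if config is None else config
    if "network" not in cfg:
        cfg = {**load_config(), **cfg}
    n = cfg["cohort"]["n"] if n is None else n
    seed = cfg["cohort"]["seed"] if seed is None else seed
    network = build_reduced_network(cfg["network"])
    numerics = _as_numerics(cfg.get("numerics"))
    subjects = sample_cohort(cfg["ranges"], n, seed)
    records: list[SubjectRecord] = []
    failures: list[dict] = []
    width = len(str(n - 1))
    for i, params in enumerate(subjects):
        sid = f"subject_{i:0{width}d}"
        try:
            records.append(simulate_subject(params, network, numerics,
                                            subject_id=sid))
        except (ConvergenceError, StabilityError) as exc:
            failures.append({"subject_id": sid, "error": str(exc)})
        if progress:
            print(f"\r{i + 1}/{n} subjects simulated", end="", flush=True)
    if progress:
        print()
    return records, failures
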