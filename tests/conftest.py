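"""Shared fixtures: analytic waves and (session-cached) simulations."""

import math

import numpy as np
import pytest

from pulsebench._defaults import MMHG
from pulsebench.config import NumericsConfig
from pulsebench.virtual_cohort import (
    ArterialNetwork,
    ArterialSegment,
    SubjectParameters,
    WindkesselOutlet,
    build_reduced_network,
    generate_cohort,
    segment_wave_speed,
    simulate_subject,
)

RHO = 1060.0


def midrange_params(**overrides) -> SubjectParameters:
    base = dict(heart_rate=75.0, stroke_volume=75.0, ejection_time=0.30,
                c_el_factor=1.0, muscular_stiffness_scale=1.0,
                diameter_scale=1.0, peripheral_resistance_scale=1.0,
                peripheral_compliance_scale=1.0)
    base.update(overrides)
    return SubjectParameters(**base)


def make_single_vessel(length=0.4, radius=0.010, h=1.2e-3, E=0.45e6,
                       r_total=1.2e8, compliance=1.0e-8,
                       pout_mmhg=5.0) -> ArterialNetwork:
    """One uniform vessel with a characteristic-impedance-matched R1."""
    seg = ArterialSegment("vessel", length, radius, radius, h, E, "elastic")
    c = segment_wave_speed(seg)
    z = RHO * c / (math.pi * radius ** 2)
    return ArterialNetwork(
        segments={"vessel": seg}, bifurcations=[], conjunctions=[],
        inlet="vessel",
        outlets={"vessel": WindkesselOutlet(z, compliance, r_total - z,
                                            pout_mmhg * MMHG)},
        sites={"prox": ("vessel", 0.1), "dist": ("vessel", 0.9)},
    )


def forward_simple_wave(c0=5.0, amplitude=0.10, radius=0.010,
                        fs=1000.0, period=0.8, pulse_len=0.30,
                        p0_mmhg=80.0, rho=RHO):
    """Analytic forward-running simple wave in a uniform elastic tube.

    Along a forward characteristic the backward invariant is constant,
    c = c0 + U/4; the tube law then gives A, P, Q, D consistently. For a
    small amplitude every local wave-speed estimator must recover ~c0.
    Returns a dict of sampled series plus the construction constants.
    """
    n = int(round(period * fs))
    t = np.arange(n) / fs
    u = np.where(t < pulse_len,
                 amplitude * np.sin(np.pi * t / pulse_len) ** 2, 0.0)
    ad = math.pi * radius ** 2
    b = 2.0 * rho * c0 ** 2 / math.sqrt(ad)
    c = c0 + u / 4.0
    a = ad * (c / c0) ** 4
    p = p0_mmhg * MMHG + b * (np.sqrt(a) - math.sqrt(ad))
    return {"t": t, "U": u, "A": a, "P": p, "Q": u * a,
            "D": 2.0 * np.sqrt(a / np.pi), "c0": c0, "rho": rho,
            "fs": fs, "b": b, "Ad": ad}


@pytest.fixture(scope="session")
def default_network():
    return build_reduced_network()


@pytest.fixture(scope="session")
def numerics():
    return NumericsConfig()


@pytest.fixture(scope="session")
def midrange_record(default_network):
    """One converged mid-range subject, with probes at the aorto-iliac
    junction nodes for flow-conservation checks."""
    probes = {"ji_parent": ("abdominal_aorta_b", 1.0),
              "ji_d1": ("iliac", 0.0),
              "ji_d2": ("iliac_contra", 0.0)}
    return simulate_subject(midrange_params(), default_network,
                            extra_probes=probes, subject_id="midrange")


@pytest.fixture(scope="session")
def single_vessel_record():
    net = make_single_vessel()
    return simulate_subject(midrange_params(), net, subject_id="vessel"), net


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort for case-study level tests (fast)."""
    records, failures = generate_cohort(n=6, seed=20161208)
    assert not failures
    return records
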