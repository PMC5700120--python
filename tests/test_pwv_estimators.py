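"""Theoretical speeds, foot detection, loop/sum-of-squares estimators,
reflection coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsebench.errors import DetectionError, DomainError, EstimationError, \
    StructuralError
from pulsebench.pwv_estimators import (
    detect_foot,
    foot_to_foot_pwv,
    loop_pwv,
    mean_reflection_coefficient,
    path_theoretical_pwv,
    reflection_coefficient,
    sum_of_squares_pwv,
    theoretical_pwv,
)
from pulsebench.virtual_cohort import (
    ArterialNetwork,
    ArterialSegment,
    WindkesselOutlet,
    segment_wave_speed,
)

from conftest import RHO, forward_simple_wave


def _segment(name="seg", L=0.1, r=0.0125, h=1.5e-3, E=0.4e6):
    return ArterialSegment(name, L, r, r, h, E, "elastic")


# --------------------------------------------------------------------------
# theoretical speeds
# --------------------------------------------------------------------------

class TestTheoreticalPWV:
    def test_closed_form(self):
        # c = sqrt((4/3) E h / (rho D)) for E=0.4 MPa, h=1.5 mm, D=25 mm
        seg = _segment()
        expected = math.sqrt((4.0 / 3.0) * 0.4e6 * 1.5e-3 / (RHO * 0.025))
        assert theoretical_pwv(seg, RHO) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.494, abs=5e-3)

    def test_scaling_with_stiffness(self):
        c1 = theoretical_pwv(_segment(E=0.4e6))
        c2 = theoretical_pwv(_segment(E=0.8e6))
        assert c2 / c1 == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DomainError):
            segment_wave_speed(_segment(), rho=-1.0)


class TestPathTheoreticalPWV:
    def _two_segment_net(self, c_fast=8.0, c_slow=4.0, L=0.2):
        # choose E so the midpoint speeds are exactly c_slow and c_fast
        def seg_for(name, c):
            r, h = 0.01, 1e-3
            E = c * c * RHO * (2 * r) * 3.0 / (4.0 * h)
            return ArterialSegment(name, L, r, r, h, E, "elastic")

        segs = {"a": seg_for("a", c_slow), "b": seg_for("b", c_fast)}
        wk = WindkesselOutlet(1e7, 1e-9, 1e8, 0.0)
        return ArterialNetwork(
            segments=segs, bifurcations=[], conjunctions=[("a", "b")],
            inlet="a", outlets={"b": wk},
            sites={"start": ("a", 0.0), "end": ("b", 1.0),
                   "mid_a": ("a", 0.5)})

    def test_harmonic_mean_of_two_segments(self):
        net = self._two_segment_net()
        # equal lengths at 4 and 8 m/s: 2L / (L/4 + L/8) = 16/3
        assert path_theoretical_pwv(net, "start", "end") == pytest.approx(
            16.0 / 3.0, rel=1e-12)

    def test_uniform_path_returns_c(self):
        net = self._two_segment_net(c_fast=4.0, c_slow=4.0)
        assert path_theoretical_pwv(net, "start", "end") == pytest.approx(4.0)

    def test_single_segment_path(self):
        net = self._two_segment_net()
        assert path_theoretical_pwv(net, "start", "mid_a") == pytest.approx(4.0)

    def test_sites_not_on_one_path_raise(self):
        net = self._two_segment_net()
        with pytest.raises(StructuralError):
            path_theoretical_pwv(net, "end", "start")


# --------------------------------------------------------------------------
# foot detection
# --------------------------------------------------------------------------

def _ramp_wave(t_foot=0.10, fs=1000.0, n=800, slope=200.0):
    t = np.arange(n) / fs
    y = np.where(t > t_foot, slope * (t - t_foot), 0.0)
    return np.minimum(y, slope * 0.25)  # plateau so the peak exists


class TestDetectFoot:
    def test_piecewise_linear_foot_exact(self):
        det = detect_foot(_ramp_wave(0.10), 1000.0)
        assert det.foot_time == pytest.approx(0.10, abs=2e-3)

    def test_shift_equivariance(self):
        d0 = detect_foot(_ramp_wave(0.10), 1000.0)
        d1 = detect_foot(_ramp_wave(0.13), 1000.0)
        assert d1.foot_time - d0.foot_time == pytest.approx(0.03, abs=1e-3)

    def test_sigmoid_foot_near_amplitude_crossing(self):
        # a physiologically steep upstroke (time scale ~1.5 ms); the
        # intersecting tangent lands 2*s before the midpoint, the 1%
        # crossing ln(99)*s before it, so they agree only for steep s
        fs = 1000.0
        t = np.arange(800) / fs
        y = 1.0 / (1.0 + np.exp(-(t - 0.15) / 0.0015))
        det = detect_foot(y, fs)
        # brute-force oracle: the 1%-amplitude crossing on a dense grid
        td = np.linspace(0, 0.799, 200000)
        yd = 1.0 / (1.0 + np.exp(-(td - 0.15) / 0.0015))
        t_1pct = td[np.argmax(yd >= yd.min() + 0.01 * (yd.max() - yd.min()))]
        assert abs(det.foot_time - t_1pct) < 5e-3

    def test_flat_signal_rejected(self):
        with pytest.raises(DetectionError):
            detect_foot(np.full(500, 3.0), 1000.0)

    def test_monotone_signal_rejected(self):
        with pytest.raises(DetectionError):
            detect_foot(np.linspace(0.0, 1.0, 500), 1000.0)


class TestFootToFoot:
    def test_pure_delay(self):
        fs = 1000.0
        w = _ramp_wave(0.10, fs)
        shifted = _ramp_wave(0.12, fs)
        est = foot_to_foot_pwv(w, shifted, 0.12, fs)
        assert est.value == pytest.approx(6.0, rel=0.01)

    def test_zero_delay_is_estimation_error(self):
        w = _ramp_wave(0.10)
        with pytest.raises(EstimationError, match="feet"):
            foot_to_foot_pwv(w, w.copy(), 0.12, 1000.0)

    def test_nonpositive_path_rejected(self):
        with pytest.raises(DomainError):
            foot_to_foot_pwv(_ramp_wave(), _ramp_wave(0.12), -0.1, 1000.0)


# --------------------------------------------------------------------------
# loop and sum-of-squares estimators on analytic waves
# --------------------------------------------------------------------------

class TestLoopEstimators:
    def test_pu_loop_water_hammer_identity(self):
        # P = Pd + rho c U with c = 5 exactly: the PU slope is exact
        fs = 1000.0
        t = np.arange(800) / fs
        u = np.where(t < 0.3, 0.8 * np.sin(np.pi * t / 0.3) ** 2, 0.0)
        p = 9000.0 + RHO * 5.0 * u
        est = loop_pwv("PU", p, u, RHO, fs)
        assert est.value == pytest.approx(5.0, rel=1e-6)

    def test_loops_consistent_on_simple_wave(self):
        w = forward_simple_wave(c0=5.0, amplitude=0.10)
        qa = loop_pwv("QA", w["Q"], w["A"], w["rho"], w["fs"]).value
        lndu = loop_pwv("lnDU", w["D"], w["U"], w["rho"], w["fs"]).value
        assert qa == pytest.approx(5.0, rel=0.01)
        assert lndu == pytest.approx(5.0, rel=0.01)

    def test_reflection_shifts_pu_up_lndu_down(self):
        # forward sigmoid + positive reflected wave arriving in the window:
        # P and U from characteristics, A from the tube law
        fs, c0 = 1000.0, 5.0
        t = np.arange(800) / fs
        f = 0.4 / (1.0 + np.exp(-(t - 0.10) / 0.015))
        g = 0.35 * 0.4 / (1.0 + np.exp(-(t - 0.13) / 0.015))
        u = f - g
        ad = math.pi * 0.01 ** 2
        b = 2.0 * RHO * c0 ** 2 / math.sqrt(ad)
        p = 10000.0 + RHO * c0 * (f + g)
        a = (math.sqrt(ad) + (p - 10000.0) / b) ** 2
        d = 2.0 * np.sqrt(a / np.pi)
        pu = loop_pwv("PU", p, u, RHO, fs).value
        lndu = loop_pwv("lnDU", d, u, RHO, fs).value
        assert pu > c0 * 1.02
        assert lndu < c0 * 0.98

    def test_window_too_short_is_estimation_error(self):
        # upstroke only 6 samples long: the window cannot reach 10 samples
        fs = 1000.0
        t = np.arange(800) / fs
        u = np.where(t < 0.1, 0.0,
                     np.where(t < 0.106, (t - 0.1) / 0.006,
                              np.maximum(0.0, 1.0 - (t - 0.106) / 0.3)))
        p = 9000.0 + RHO * 5.0 * u
        with pytest.raises(EstimationError):
            loop_pwv("PU", p, u, RHO, fs)

    def test_unknown_variant_rejected(self):
        with pytest.raises(DomainError):
            loop_pwv("XY", np.zeros(100), np.zeros(100))


class TestSumOfSquares:
    def test_water_hammer_exact(self):
        w = forward_simple_wave(amplitude=0.02)
        # construct dP = rho c0 dU exactly
        p = 9000.0 + RHO * w["c0"] * w["U"]
        est = sum_of_squares_pwv(p, w["U"], RHO, w["fs"])
        assert est.value == pytest.approx(w["c0"], rel=1e-12)

    def test_constant_velocity_is_error(self):
        with pytest.raises(EstimationError, match="constant"):
            sum_of_squares_pwv(np.linspace(0, 1, 100), np.zeros(100), RHO)

    def test_equal_energy_separated_pulses_give_c(self):
        # forward increments then backward increments, non-overlapping:
        # each obeys |dP| = rho c |dU|, so the ratio is exactly c
        c = 6.0
        duf = np.concatenate([np.full(50, 1e-3), np.zeros(50)])
        dub = np.concatenate([np.zeros(50), np.full(50, 1e-3)])
        dp = RHO * c * (duf + dub)
        du = duf - dub
        p = np.concatenate([[0.0], np.cumsum(dp)])
        u = np.concatenate([[0.0], np.cumsum(du)])
        est = sum_of_squares_pwv(p, u, RHO, 1000.0)
        assert est.value == pytest.approx(c, rel=1e-12)

    def test_overlapping_anticorrelated_increments_overestimate(self):
        c = 6.0
        duf = np.full(100, 1e-3)
        dub = np.full(100, 0.5e-3)  # simultaneous backward wave
        dp = RHO * c * (duf + dub)
        du = duf - dub
        p = np.concatenate([[0.0], np.cumsum(dp)])
        u = np.concatenate([[0.0], np.cumsum(du)])
        est = sum_of_squares_pwv(p, u, RHO, 1000.0)
        assert est.value > c * 1.5


# --------------------------------------------------------------------------
# reflection coefficients
# --------------------------------------------------------------------------

class TestReflectionCoefficient:
    def test_matched_bifurcation_is_zero(self):
        # Yp = Yd1 + Yd2: equal areas and speeds chosen accordingly
        r = reflection_coefficient(2e-4, 5.0, 1e-4, 5.0, 1e-4, 5.0)
        assert r.Rt == pytest.approx(0.0, abs=1e-14)

    def test_direct_evaluation_one_third(self):
        # Yp=2, Yd1=Yd2=0.5 (arbitrary units via rho=1, c=1, A=Y)
        r = reflection_coefficient(2.0, 1.0, 0.5, 1.0, 0.5, 1.0, rho=1.0)
        assert r.Rt == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_closed_end_limit(self):
        r = reflection_coefficient(2e-4, 5.0, 1e-10, 5.0, 1e-10, 5.0)
        assert r.Rt == pytest.approx(1.0, abs=1e-5)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DomainError):
            reflection_coefficient(2e-4, -5.0, 1e-4, 5.0, 1e-4, 5.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10))
    def test_role_swap_antisymmetry(self, yp, y1, y2):
        # swapping "parent" and "combined daughters" flips the sign
        fwd = reflection_coefficient(yp, 1.0, y1, 1.0, y2, 1.0, rho=1.0).Rt
        rev = reflection_coefficient(y1 + y2, 1.0, yp / 2, 1.0, yp / 2, 1.0,
                                     rho=1.0).Rt
        assert rev == pytest.approx(-fwd, rel=1e-9, abs=1e-12)
        assert -1.0 <= fwd <= 1.0


class TestMeanReflection:
    def _net_with_rts(self, default_network):
        return default_network

    def test_mean_matches_bruteforce(self, default_network):
        mean = mean_reflection_coefficient(default_network)
        total = 0.0
        for p, d1, d2 in default_network.bifurcations:
            sp = default_network.segments[p]
            s1 = default_network.segments[d1]
            s2 = default_network.segments[d2]
            total += reflection_coefficient(
                sp.area_at(1.0), segment_wave_speed(sp, s=1.0),
                s1.area_at(0.0), segment_wave_speed(s1, s=0.0),
                s2.area_at(0.0), segment_wave_speed(s2, s=0.0)).Rt
        assert mean == pytest.approx(
            total / len(default_network.bifurcations), rel=1e-12)

    def test_network_without_bifurcations_rejected(self):
        from conftest import make_single_vessel
        with pytest.raises(DomainError):
            mean_reflection_coefficient(make_single_vessel())


# --------------------------------------------------------------------------
# behaviour on simulated waves
# --------------------------------------------------------------------------

def test_qa_close_to_lndu_on_simulated_subject(midrange_record):
    """QA and lnDU differ by the early-systolic velocity (small), far less
    than either deviates from the PU loop at reflective sites."""
    rec = midrange_record
    wf = rec.waveforms
    fs = wf.sampling_rate
    rho = rec.parameters.blood_density
    for site in ("carotid", "iliac"):
        qa = loop_pwv("QA", wf.flow(site), wf.area(site), rho, fs).value
        lndu = loop_pwv("lnDU", wf.diameter(site), wf.velocity(site),
                        rho, fs).value
        pu = loop_pwv("PU", wf.pressure(site), wf.velocity(site),
                      rho, fs).value
        assert qa >= lndu  # QA - lnDU = U in the window > 0
        assert abs(qa - lndu) < 0.6
        assert abs(qa - lndu) < abs(pu - lndu)
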