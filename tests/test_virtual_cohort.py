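"""Network construction, cohort sampling, solver physics, waveform I/O."""

import math

import numpy as np
import pytest

from pulsebench._defaults import DEFAULT_RANGES, MMHG, default_config
from pulsebench.errors import (
    ConfigError,
    DomainError,
    FormatError,
    StructuralError,
)
from pulsebench.io import read_subject, write_subject
from pulsebench.pwv_estimators import detect_foot, foot_to_foot_pwv
from pulsebench.virtual_cohort import (
    ArterialNetwork,
    ArterialSegment,
    InflowWaveform,
    WindkesselOutlet,
    build_reduced_network,
    sample_cohort,
    segment_wave_speed,
    simulate_subject,
)

from conftest import make_single_vessel, midrange_params


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

class TestBuildNetwork:
    def test_default_network_contract(self, default_network):
        net = default_network
        assert net.inlet == "ascending_aorta"
        assert len(net.segments) >= 12
        for leaf in net.leaves:
            assert leaf in net.outlets
        # required measurement sites exist
        for site in ("ascending_aorta", "thoracic_aorta",
                     "abdominal_aorta_distal", "carotid", "brachial",
                     "iliac", "femoral", "ankle"):
            assert site in net.sites

    def test_path_lengths_increase_downstream(self, default_network):
        net = default_network
        for leaf in net.leaves:
            chain = net.path_segments(leaf)
            lengths = [net.path_length_to(seg, 1.0) for seg in chain]
            assert all(b > a for a, b in zip(lengths, lengths[1:]))

    def test_single_vessel_network(self):
        net = make_single_vessel(length=0.25)
        assert net.path_length_to("vessel", 1.0) == pytest.approx(0.25)

    def test_duplicate_daughter_is_structural_error(self):
        seg = dict(length=0.1, radius_prox=5e-3, radius_dist=4e-3,
                   wall_thickness=5e-4, youngs_modulus=5e5)
        segs = {n: ArterialSegment(name=n, **seg) for n in "abc"}
        wk = WindkesselOutlet(1e7, 1e-9, 1e8, 0.0)
        with pytest.raises(StructuralError, match="twice"):
            ArterialNetwork(segments=segs, bifurcations=[("a", "b", "b")],
                            conjunctions=[], inlet="a",
                            outlets={"b": wk, "c": wk})

    @pytest.mark.parametrize("mutate, match", [
        (lambda d: d["children"].update({"tibial": ["ascending_aorta"]}),
         "parent|cycle"),
        (lambda d: d["children"].pop("iliac"), "no outlet|fraction"),
        (lambda d: d.update(inlet="nonexistent"), "inlet"),
    ])
    def test_invalid_topologies(self, mutate, match):
        cfg = default_config()["network"]
        mutate(cfg)
        with pytest.raises(StructuralError, match=match):
            build_reduced_network(cfg)

    def test_invalid_segment_geometry(self):
        with pytest.raises(DomainError):
            ArterialSegment("bad", -0.1, 5e-3, 4e-3, 5e-4, 5e5)
        with pytest.raises(DomainError):
            ArterialSegment("bad", 0.1, 5e-3, 4e-3, 5e-4, -5e5)


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

class TestSampleCohort:
    def test_seed_determinism(self):
        a = sample_cohort(DEFAULT_RANGES, 3, seed=7)
        b = sample_cohort(DEFAULT_RANGES, 3, seed=7)
        assert a == b

    def test_degenerate_ranges_give_identical_subjects(self):
        ranges = {k: [0.5 * (lo + hi)] * 2
                  for k, (lo, hi) in DEFAULT_RANGES.items()}
        subs = sample_cohort(ranges, 4, seed=0)
        assert all(s.heart_rate == subs[0].heart_rate for s in subs)
        assert all(s.c_el_factor == subs[0].c_el_factor for s in subs)

    def test_values_inside_ranges_and_stiffness_spread(self):
        subs = sample_cohort(DEFAULT_RANGES, 50, seed=11)
        for key, (lo, hi) in DEFAULT_RANGES.items():
            vals = np.array([getattr(s, key) for s in subs])
            assert vals.min() >= lo and vals.max() <= hi
        c_el = np.array([s.c_el_factor for s in subs])
        lo, hi = DEFAULT_RANGES["c_el_factor"]
        # Latin hypercube at n=50 must span the stiffness range well
        assert c_el.min() < lo + 0.1 * (hi - lo)
        assert c_el.max() > hi - 0.1 * (hi - lo)

    def test_inverted_range_is_config_error(self):
        bad = {k: list(v) for k, v in DEFAULT_RANGES.items()}
        bad["heart_rate"] = [90.0, 60.0]
        with pytest.raises(ConfigError, match="inverted"):
            sample_cohort(bad, 5, seed=0)


# --------------------------------------------------------------------------
# inflow
# --------------------------------------------------------------------------

@pytest.mark.parametrize("hr, sv, tej", [(75, 75, 0.30), (60, 95, 0.35),
                                         (90, 55, 0.25)])
def test_inflow_volume_and_diastole(hr, sv, tej):
    w = InflowWaveform(period=60.0 / hr, ejection_time=tej,
                       stroke_volume=sv * 1e-6)
    t, q = w.samples(10000.0)
    vol = np.trapezoid(q, t)
    assert vol == pytest.approx(sv * 1e-6, rel=1e-3)
    diastole = t > tej + w.backflow_duration
    assert np.all(q[diastole] == 0.0)


# --------------------------------------------------------------------------
# solver physics
# --------------------------------------------------------------------------

class TestSingleVessel:
    def test_transit_time_matches_theory(self, single_vessel_record):
        rec, net = single_vessel_record
        wf = rec.waveforms
        c = segment_wave_speed(net.segments["vessel"])
        dl = net.path_length_to("vessel", 0.9) - net.path_length_to("vessel", 0.1)
        est = foot_to_foot_pwv(wf.pressure("prox"), wf.pressure("dist"),
                               dl, wf.sampling_rate, theoretical=c)
        assert abs(est.relative_error) < 0.03

    def test_mean_pressure_matches_windkessel(self, single_vessel_record):
        rec, net = single_vessel_record
        wf = rec.waveforms
        wk = net.outlets["vessel"]
        q_mean = wf.flow("prox").mean()
        predicted = wk.outflow_pressure + q_mean * wk.total_resistance
        assert wf.pressure("prox").mean() == pytest.approx(predicted, rel=0.02)

    def test_grid_convergence_of_transit_time(self):
        net = make_single_vessel()
        times = []
        for dx in (2.5e-3, 1.25e-3):
            rec = simulate_subject(midrange_params(), net, {"dx": dx})
            wf = rec.waveforms
            fp = detect_foot(wf.pressure("prox"), wf.sampling_rate)
            fd = detect_foot(wf.pressure("dist"), wf.sampling_rate)
            times.append(fd.foot_time - fp.foot_time)
        assert abs(times[1] - times[0]) / times[0] < 0.02

    def test_zero_stroke_volume_settles_at_outflow_pressure(self):
        net = make_single_vessel()
        rec = simulate_subject(midrange_params(stroke_volume=0.0), net)
        pout = net.outlets["vessel"].outflow_pressure
        for site in ("prox", "dist"):
            assert np.abs(rec.waveforms.pressure(site) - pout).max() \
                < 0.5 * MMHG


class TestDefaultNetworkPhysics:
    def test_physiological_pressure_band(self, midrange_record):
        P = midrange_record.waveforms.pressure("aortic_root") / MMHG
        assert 60.0 < P.min() < 90.0      # DBP
        assert 100.0 < P.max() < 160.0    # SBP

    def test_periodicity(self, midrange_record):
        wf = midrange_record.waveforms
        for site in wf.sites:
            P = wf.pressure(site)
            assert abs(P[0] - P[-1]) < 0.5 * MMHG

    def test_bifurcation_flow_conservation(self, midrange_record):
        wf = midrange_record.waveforms
        qp = wf.flow("ji_parent")
        qd = wf.flow("ji_d1") + wf.flow("ji_d2")
        assert np.abs(qp - qd).max() < 0.01 * np.abs(qp).max()

    def test_tube_law_slope_matches_theoretical_pwv(self, midrange_record):
        rho = midrange_record.parameters.blood_density
        for name, seg in midrange_record.network.segments.items():
            c_stored = midrange_record.theoretical_pwv[name]
            # independent Bramwell-Hill oracle: numeric dP/dA at A_d
            ad = seg.area_at(0.5)
            b = seg.beta / ad

            def tube_p(a):
                return b * (math.sqrt(a) - math.sqrt(ad))

            h = 1e-6 * ad
            dpda = (tube_p(ad + h) - tube_p(ad - h)) / (2 * h)
            c_bh = math.sqrt(ad / rho * dpda)
            assert c_bh == pytest.approx(c_stored, rel=0.005)

    def test_mean_inlet_pressure_against_equivalent_resistance(
            self, midrange_record):
        # total equivalent resistance = parallel Windkessels plus the
        # Poiseuille-type series resistance of the 1D vessels (small but
        # not negligible in the distal limbs)
        wf = midrange_record.waveforms
        net = midrange_record.network
        q_mean = wf.flow("aortic_root").mean()
        r_wk = net.total_peripheral_resistance()
        p_mean = wf.pressure("aortic_root").mean()
        pout = next(iter(net.outlets.values())).outflow_pressure
        r_eff = (p_mean - pout) / q_mean
        assert r_wk < r_eff < 1.35 * r_wk


# --------------------------------------------------------------------------
# waveform I/O
# --------------------------------------------------------------------------

class TestWaveformIO:
    def test_round_trip(self, midrange_record, tmp_path):
        write_subject(midrange_record, tmp_path)
        back = read_subject(tmp_path / "midrange.csv")
        assert back.subject_id == midrange_record.subject_id
        assert back.parameters == midrange_record.parameters
        assert back.theoretical_pwv == pytest.approx(
            midrange_record.theoretical_pwv)
        wf0, wf1 = midrange_record.waveforms, back.waveforms
        assert wf1.sites == wf0.sites
        for site in wf0.sites:
            for getter in ("pressure", "flow", "area"):
                a = getattr(wf0, getter)(site)
                b = getattr(wf1, getter)(site)
                assert np.allclose(a, b, rtol=1e-9, atol=0.0)

    def test_missing_column_is_format_error(self, midrange_record, tmp_path):
        import pandas as pd
        write_subject(midrange_record, tmp_path)
        csv = tmp_path / "midrange.csv"
        df = pd.read_csv(csv)
        df.drop(columns=["carotid_A_cm2"]).to_csv(csv, index=False)
        with pytest.raises(FormatError, match="carotid_A_cm2"):
            read_subject(csv)

    def test_hand_written_toy_file(self, tmp_path):
        import json
        (tmp_path / "toy.csv").write_text(
            "time_s,aorta_P_mmHg,aorta_Q_mls,aorta_A_cm2\n"
            "0,80,0,5\n0.001,90,100,5.1\n0.002,85,50,5.05\n")
        meta = {"subject_id": "toy", "sampling_rate": 1000.0,
                "period": 0.003, "sites": ["aorta"],
                "path_lengths": {}, "theoretical_pwv": {},
                "parameters": {"heart_rate": 75, "stroke_volume": 75,
                               "ejection_time": 0.3, "c_el_factor": 1,
                               "muscular_stiffness_scale": 1,
                               "diameter_scale": 1,
                               "peripheral_resistance_scale": 1,
                               "peripheral_compliance_scale": 1},
                "network": {
                    "segments": {"aorta": {
                        "length": 0.1, "radius_prox": 0.013,
                        "radius_dist": 0.012, "wall_thickness": 1.5e-3,
                        "youngs_modulus": 4e5, "wall_class": "elastic"}},
                    "bifurcations": [], "conjunctions": [],
                    "inlet": "aorta",
                    "outlets": {"aorta": {
                        "proximal_resistance": 1e7, "compliance": 1e-9,
                        "distal_resistance": 1e8, "outflow_pressure": 0.0}},
                    "sites": {"aorta": ["aorta", 0.5]}}}
        (tmp_path / "toy.json").write_text(json.dumps(meta))
        rec = read_subject(tmp_path / "toy.csv")
        assert rec.waveforms.pressure("aorta") == pytest.approx(
            np.array([80, 90, 85]) * MMHG)
        assert rec.waveforms.flow("aorta") == pytest.approx(
            np.array([0, 100, 50]) * 1e-6)
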