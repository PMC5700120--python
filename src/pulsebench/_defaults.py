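"""Built-in default configuration: the reduced arterial network and cohort
parameter ranges.

The default network is a 17-segment reduction of the human systemic tree:
a tapered aorta (ascending, arch, thoracic, abdominal), one carotid
ending at its internal/external bifurcation (the dominant positive
reflection site of the head), one
subclavian-brachial arm path, both iliacs, and one leg continued to the
ankle (femoral -> tibial, with a profunda branch draining the thigh).
Baseline dimensions and stiffnesses are standard adult values; each leaf
terminates in an RCR Windkessel whose resistances are apportioned by the
fraction of cardiac output that bed receives.

Geometry is given at the reference (diastolic) state: radii are the lumen
radii at the reference pressure ``numerics.p_ref_mmhg``.
"""

# name: [length_m, r_prox_m, r_dist_m, wall_h_m, E_Pa, wall_class]
# subclavian/brachial are the two arms lumped: radii are sqrt(2) times a
# single-side vessel so the combined cross-section (and hence the viscous
# drop at the combined flow) matches reality
DEFAULT_SEGMENTS = {
    "ascending_aorta":   [0.050, 0.0138, 0.0130, 1.50e-3, 0.37e6, "elastic"],
    "aortic_arch_a":     [0.025, 0.0130, 0.0126, 1.50e-3, 0.40e6, "elastic"],
    "carotid":           [0.120, 0.0040, 0.0037, 0.65e-3, 0.55e6, "elastic"],
    "internal_carotid":  [0.120, 0.0025, 0.0020, 0.50e-3, 0.70e6, "elastic"],
    "external_carotid":  [0.100, 0.0020, 0.0016, 0.45e-3, 0.80e6, "muscular"],
    "aortic_arch_b":     [0.035, 0.0126, 0.0120, 1.40e-3, 0.40e6, "elastic"],
    "subclavian":        [0.120, 0.0059, 0.0052, 0.75e-3, 0.70e6, "elastic"],
    "brachial":          [0.250, 0.0052, 0.0044, 0.70e-3, 0.80e6, "muscular"],
    "thoracic_aorta_a":  [0.090, 0.0118, 0.0105, 1.30e-3, 0.43e6, "elastic"],
    "thoracic_aorta_b":  [0.100, 0.0105, 0.0095, 1.20e-3, 0.47e6, "elastic"],
    "abdominal_aorta_a": [0.080, 0.0095, 0.0085, 1.10e-3, 0.50e6, "elastic"],
    "abdominal_aorta_b": [0.080, 0.0085, 0.0072, 1.00e-3, 0.55e6, "elastic"],
    "iliac":             [0.140, 0.0058, 0.0046, 0.70e-3, 0.70e6, "elastic"],
    "iliac_contra":      [0.120, 0.0058, 0.0046, 0.70e-3, 0.70e6, "elastic"],
    "femoral":           [0.250, 0.0044, 0.0037, 0.65e-3, 0.90e6, "muscular"],
    "profunda":          [0.120, 0.0033, 0.0027, 0.60e-3, 1.00e6, "muscular"],
    "tibial":            [0.350, 0.0038, 0.0030, 0.60e-3, 1.20e6, "muscular"],
}

# parent -> daughters (two entries = bifurcation, one = conjunction)
DEFAULT_CHILDREN = {
    "ascending_aorta": ["aortic_arch_a", "carotid"],
    "carotid": ["internal_carotid", "external_carotid"],
    "aortic_arch_a": ["aortic_arch_b", "subclavian"],
    "aortic_arch_b": ["thoracic_aorta_a"],
    "thoracic_aorta_a": ["thoracic_aorta_b"],
    "thoracic_aorta_b": ["abdominal_aorta_a"],
    "abdominal_aorta_a": ["abdominal_aorta_b"],
    "abdominal_aorta_b": ["iliac", "iliac_contra"],
    "subclavian": ["brachial"],
    "iliac": ["femoral"],
    "femoral": ["tibial", "profunda"],
}

DEFAULT_INLET = "ascending_aorta"

# Terminal Windkessels: total systemic values split by flow fraction.
# R1 is capped at min(terminal characteristic impedance, r1_cap * R_total_i)
# so the lumped leg/arm beds keep a positive distal resistance.
DEFAULT_WINDKESSEL = {
    "total_resistance": 1.08e8,     # Pa s / m^3  (MAP ~95 mmHg at CO 5.6 L/min,
                                    # net of the 1D viscous series resistance)
    "total_compliance": 1.35e-8,    # m^3 / Pa    (terminal part, ~1.8 mL/mmHg)
    "outflow_pressure_mmhg": 5.0,   # venous pressure
    "r1_cap_fraction": 0.4,
    "flow_fractions": {
        "internal_carotid": 0.10,
        "external_carotid": 0.06,
        "brachial": 0.14,
        "iliac_contra": 0.35,
        "tibial": 0.12,
        "profunda": 0.23,
    },
}

# named measurement sites: segment and relative position along it
DEFAULT_SITES = {
    "aortic_root":            ["ascending_aorta", 0.0],
    "ascending_aorta":        ["ascending_aorta", 0.5],
    "descending_aorta":       ["thoracic_aorta_a", 0.1],
    "thoracic_aorta":         ["thoracic_aorta_b", 0.5],
    "abdominal_aorta_distal": ["abdominal_aorta_b", 0.95],
    "carotid":                ["carotid", 0.5],
    "brachial":               ["brachial", 0.5],
    "iliac":                  ["iliac", 0.5],
    "femoral":                ["femoral", 0.15],
    "ankle":                  ["tibial", 0.98],
}

# healthy sampling ranges for the virtual cohort
DEFAULT_RANGES = {
    "heart_rate": [60.0, 90.0],            # bpm
    "stroke_volume": [55.0, 95.0],         # mL
    "ejection_time": [0.25, 0.35],         # s
    "c_el_factor": [0.7, 1.7],             # scales E*h of elastic segments
    "muscular_stiffness_scale": [0.8, 1.4],
    "diameter_scale": [0.9, 1.1],
    "peripheral_resistance_scale": [0.7, 1.3],
    "peripheral_compliance_scale": [0.7, 1.3],
}

DEFAULT_NUMERICS = {
    "dx": 2.5e-3,            # m
    "cfl": 0.9,
    "blood_viscosity": 4.0e-3,   # Pa s
    "profile_zeta": 9.0,     # axisymmetric velocity-profile constant
    "p_ref_mmhg": 75.0,      # pressure at which lumen area equals reference area
    "max_cycles": 30,
    "min_cycles": 5,
    "periodicity_tol_mmhg": 0.1,
    "output_rate": 1000.0,   # Hz of emitted waveforms
    "backflow_fraction": 0.02,   # end-systolic backflow volume / forward volume
    "backflow_duration": 0.06,   # s
    "ejection_rise_fraction": 0.3,   # fraction of ejection time to peak flow
}

DEFAULT_COHORT = {"n": 50, "seed": 20161208}

BLOOD_DENSITY = 1060.0  # kg/m^3
MMHG = 133.322          # Pa per mmHg


def default_config() -> dict:
    """Full default configuration as a plain nested dict."""
    return {
        "network": {
            "segments": {k: list(v) for k, v in DEFAULT_SEGMENTS.items()},
            "children": {k: list(v) for k, v in DEFAULT_CHILDREN.items()},
            "inlet": DEFAULT_INLET,
            "windkessel": {
                **{k: v for k, v in DEFAULT_WINDKESSEL.items() if k != "flow_fractions"},
                "flow_fractions": dict(DEFAULT_WINDKESSEL["flow_fractions"]),
            },
            "sites": {k: list(v) for k, v in DEFAULT_SITES.items()},
        },
        "ranges": {k: list(v) for k, v in DEFAULT_RANGES.items()},
        "numerics": dict(DEFAULT_NUMERICS),
        "cohort": dict(DEFAULT_COHORT),
    }
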