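# pulsebench

Virtual arterial pulse-wave cohorts for benchmarking hemodynamic
indexes.

Clinical tools built on pulse wave analysis — pulse wave velocity (PWV)
estimators, central blood pressure reconstruction, the augmentation
index — are hard to validate in vivo because their "true" value is never
measurable. pulsebench takes the in-silico route: it generates cohorts
of *virtual subjects* with a reduced 1D model of the systemic arteries
in which every quantity (wave speed of every segment, pressure/flow/area
everywhere) is known exactly, then runs the clinical algorithms against
those exact references. It is aimed at researchers in cardiovascular
biomechanics and physiological signal processing who want a controlled,
reproducible test bed for pulse-wave algorithms.

## What is inside

* **`virtual_cohort`** — a 17-segment elastic-tube reduction of the
  adult arterial tree (aorta, carotid with its cerebral bifurcation,
  arm, both iliacs, one leg to the ankle), solved with a MacCormack
  scheme under the tube law `P = p_ref + (β/A_d)(√A − √A_d)`,
  `β = (4/3)√π E h`, so each segment's theoretical wave speed is the
  Moens–Korteweg speed `c = √(β / 2ρ√A_d)`. Ventricular inflow at the
  root, RCR Windkessels at the leaves, Latin-hypercube sampling of
  heart rate, stroke volume, ejection time, wall stiffness, diameter
  and peripheral scales within healthy ranges.
* **`pwv_estimators`** — foot-to-foot PWV (intersecting-tangent feet,
  `ΔL/Δt`), the loop estimators `PWV_PU = (1/ρ) dP/dU`,
  `PWV_QA = dQ/dA`, `PWV_lnDU = ½ dU/d lnD` over the linear
  early-systolic window, the sum-of-squares estimator
  `(1/ρ)√(ΣdP²/ΣdU²)`, and bifurcation reflection coefficients
  `Rt = (Yp − Yd1 − Yd2)/(Yp + Yd1 + Yd2)` with `Y = A/(ρc)`.
* **`central_pressure`** — reconstruction of the aortic pressure wave
  from non-invasive inputs: a water-hammer upstroke
  `P = DBP + ρ·PWV·U(t)`, a late-systolic quadratic constrained by
  continuity and conservation of mean pressure, and the peripheral
  diastolic decay; plus the systolic-shoulder error
  `ε = P1_algo − P1_ref`.
* **`wave_analysis`** — systolic-shoulder detection (Savitzky–Golay
  fourth derivative, order 6 over 35 points at 1 kHz), augmentation
  index, and linear forward/backward wave separation
  `dP_f,b = (dP ± ρc dU)/2`.
* **`case_studies`** — the three cohort-level benchmarks: estimator
  accuracy vs theoretical PWV, shoulder error for seven PWV input
  variants, and AIx vs wave-reflection measures, with tidy CSV/JSON
  reports and optional figures.

## Worked example

```python
from pulsebench import build_reduced_network, simulate_subject
from pulsebench.virtual_cohort import SubjectParameters
from pulsebench import pwv_estimators as pwv
from pulsebench import wave_analysis as wa

net = build_reduced_network()
subject = SubjectParameters(
    heart_rate=75, stroke_volume=75, ejection_time=0.30,
    c_el_factor=1.2, muscular_stiffness_scale=1.0, diameter_scale=1.0,
    peripheral_resistance_scale=1.0, peripheral_compliance_scale=1.0)
rec = simulate_subject(subject, net)      # converged periodic waveforms
wf = rec.waveforms

dl = net.path_lengths["abdominal_aorta_distal"] - net.path_lengths["aortic_root"]
est = pwv.foot_to_foot_pwv(
    wf.pressure("aortic_root"), wf.pressure("abdominal_aorta_distal"),
    dl, wf.sampling_rate,
    theoretical=pwv.path_theoretical_pwv(rec.network, "aortic_root",
                                         "abdominal_aorta_distal"))
aix = wa.augmentation_index(wf.pressure("carotid"), wf.sampling_rate)
```

prints (via the accessors shown in `scripts/` and the test suite):

```
aortic root pressure: 73/137 mmHg (mean 100)
aortic foot-to-foot PWV: 6.46 m/s (theoretical 6.39, error +1.1%)
sum-of-squares PWV (ascending aorta): 7.28 m/s (error +30%)
carotid AIx: 0.43 (shoulder at 83 ms, P1 107 mmHg)
```

This subject has 20%-stiffened elastic arteries (`c_el_factor=1.2`):
foot-to-foot PWV along the aorta tracks the transit-time-averaged
theoretical speed closely, while the single-site sum-of-squares
estimator over-reads by ~30% because it is contaminated by reflected
waves — the kind of estimator bias the package exists to quantify.

## Command line

```sh
pulsebench generate --out cohort/ --n 50 --seed 20161208
pulsebench pwv --cohort cohort/ --out case1.csv
pulsebench cbp --cohort cohort/ --out case2.csv
pulsebench aix --cohort cohort/ --out case3.csv
pulsebench run-all --out results/ --plots
```

Cohorts are directories of per-subject CSV waveform files
(`time_s`, `<site>_P_mmHg`, `<site>_Q_mls`, `<site>_A_cm2`) with JSON
sidecars carrying parameters, the scaled network and theoretical wave
speeds, plus a `cohort_manifest.csv`.

## Reproduction benchmarks

`scripts/acceptance.py` regenerates the default 50-subject cohort from
scratch and recomputes the headline cohort statistics of the three case
studies (foot-to-foot and loop/sum-of-squares biases, shoulder-error
means per PWV variant, AIx–reflection correlations):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is about a minute on one CPU. `tests/test_acceptance.py` runs
the same statistics against their reference values alongside the hard
property-based criteria; `docs/methods.md` documents which reproductions
the reduced network can and cannot support and why.
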