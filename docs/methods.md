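# Methods

## The model

pulsebench simulates pulse propagation in a branching network of tapered,
thin-walled, incompressible elastic tubes. Per segment, with lumen area
`A(x,t)` and cross-sectionally averaged velocity `U(x,t)`:

    A_t + (A U)_x = 0
    U_t + (U^2/2 + P/rho)_x = -2 (zeta + 2) pi mu U / (rho A)

closed by the elastic tube law

    P = p_ref + (beta / A_d(x)) (sqrt(A) - sqrt(A_d(x))),
    beta = (4/3) sqrt(pi) E h,

where `A_d(x)` is the lumen area at the reference pressure `p_ref`
(default 75 mmHg, i.e. a typical diastolic state) and `E h` the wall
stiffness per unit length. The local wave speed is
`c^2 = beta sqrt(A) / (2 rho A_d)`; at the reference area this equals the
Moens–Korteweg speed `sqrt((4/3) E h / (rho D))` of an incompressible
thin wall, and it is this reference-state value the package reports as
the *theoretical PWV* of a segment (evaluated at the segment midpoint).
The friction term assumes a fixed axisymmetric velocity profile with
shape constant `zeta = 9` and viscosity `mu = 4 mPa s`.

Boundary conditions: prescribed ventricular outflow at the aortic root;
continuity of mass and total pressure (Newton-solved on the Riemann
invariants `W± = U ± 4c`) at bifurcations and in-line joints; an RCR
Windkessel (proximal resistance, compliance, distal resistance, venous
outflow pressure) at every leaf, advanced with implicit Euler.

Numerics: two-step MacCormack (forward predictor / backward corrector)
on per-segment uniform grids, `dx ≈ 2.5 mm`, one global CFL-limited time
step (CFL 0.9 against the stiffest node with margin for systolic
distension and advection). Cycles are repeated — compliance pressures
initialised at the estimated mean pressure to shorten the transient —
until the cycle-to-cycle pressure change at every measurement site falls
below 0.1 mmHg (at least 5, at most 30 cycles). The converged cycle is
resampled to 1 kHz for analysis. Halving `dx` changes foot-to-foot
transit times by < 2% (tested).

## The reduced network

The default tree has 17 segments: ascending aorta, two arch segments,
two thoracic and two abdominal aortic segments; a common carotid ending
at its internal/external bifurcation; a subclavian–brachial arm path;
both common iliacs, one continued through femoral to a tibial (ankle)
path with a profunda branch draining the thigh. Dimensions are standard
adult values at the reference state; the subclavian/brachial path lumps
the two arms at their combined cross-section (radius × √2) so the
viscous drop at the combined flow matches a single real arm, keeping the
brachial calibration pressures within ~2 mmHg of aortic values. Wall
classes follow standard histology — aorta, carotids, subclavian and
iliacs elastic; external carotid, brachial, femoral, profunda and tibial
muscular — and determine which stiffness scale factor applies.

Terminal Windkessels divide a total peripheral resistance of
1.08·10⁸ Pa s/m³ and compliance of 1.35·10⁻⁸ m³/Pa by bed flow
fractions (head 16%, arms 14%, contralateral leg 35%, thigh 23%,
lower leg 12%); R1 is the terminal characteristic impedance capped at
0.4 of the bed total. These totals were calibrated once, before any
benchmark statistic was computed, to textbook values: mid-range cardiac
output 5.6 L/min gives aortic MAP ≈ 96 mmHg, 72/128 mmHg at the root.

The resulting bifurcation reflection coefficients
(`Rt = (Yp − Yd1 − Yd2)/(Yp + Yd1 + Yd2)`, `Y = A/(rho c)`, parent
evaluated at its distal end, daughters at their proximal ends) reproduce
the qualitative structure reported for full-anatomy trees: slightly
negative along the aorta and at the limb branchings (−0.01 … −0.26),
clearly positive at the carotid bifurcation (+0.26), near zero at the
aorto-iliac junction.

## The virtual cohort

Subjects are Latin-hypercube samples (scipy QMC, seeded) of eight
parameters within healthy adult ranges: heart rate 60–90 bpm, stroke
volume 55–95 mL, ejection time 0.25–0.35 s, elastic stiffness scale
0.7–1.7 (multiplies `E h` of elastic segments), muscular stiffness scale
0.8–1.4, diameter scale 0.9–1.1, peripheral resistance and compliance
scales 0.7–1.3. Blood density is fixed at 1060 kg/m³. The default cohort
is n = 50, seed 20161208.

The ventricular inflow is a skewed smoothstep ejection: a half-cosine
rise over 30% of the ejection time to the peak flow `2·V/Te`, a
half-cosine fall, then a brief backflow notch (2% of forward volume over
60 ms) and zero diastolic flow. A symmetric half-sine was tried first
and rejected: its maximum acceleration at `t = 0` and late flow peak
produce a sluggish, shoulder-less pressure upstroke, while the skewed
shape (matching measured aortic outflow) yields type-A waves with a
distinct systolic shoulder.

What the generator does **not** emulate: the full 55-artery anatomy
(coronary, cerebral, visceral, hand vessels), viscoelastic wall
behaviour, subject height variation, measurement noise, and type-C
(young, non-augmented) waveforms. A green cohort-level test therefore
establishes correctness of the algorithms on smooth, noise-free, type-A
waves from a compact reflection topology — not equivalence with a
full-anatomy database (see Known limitations).

## Analysis algorithms

**Foot detection (intersecting tangent).** After a 5-sample moving
average (periodic), the tangent at the point of maximum upstroke slope —
searched before the global peak so secondary features such as the
end-systolic flow notch cannot capture it; ties resolve to the earliest
sample — is intersected with the horizontal through the diastolic
minimum of the preceding quarter cycle. Foot-to-foot PWV is the
path-length difference from the inlet divided by the foot delay.

**Loop PWV (PU, QA, lnDU).** Least-squares slope over the early-systolic
linear part of the loop: the window starts at the foot of the
faster-rising series, grows sample-by-sample while the running fit keeps
R² ≥ 0.99 (minimum 10 samples), and is capped at the peak first
derivative of the rapidly-rising series (P for PU, Q for QA, U for
lnDU). `PWV_PU = (1/rho) dP/dU`, `PWV_QA = dQ/dA`,
`PWV_lnDU = (1/2) dU/d lnD`.

**Sum-of-squares.** `(1/rho) sqrt(sum dP² / sum dU²)` over
successive-sample increments of one full cycle.

**Systolic shoulder.** The pressure wave (resampled to 1 kHz if needed)
is low-passed with a periodic Gaussian spectral taper (−3 dB at 30 Hz) —
necessary because the fourth derivative amplifies a ripple of amplitude
`a` at frequency `f` by `a (2πf)⁴`, so sub-0.001-mmHg grid-scale solver
ripple would otherwise dominate, and a brick-wall cutoff rings (Gibbs)
and creates spurious crossings; crossing positions are stable under the
cutoff choice (checked at 20/30/40 Hz). The fourth derivative is then
taken with a Savitzky–Golay filter (order 6, 35 points) on the
periodically extended wave, and the shoulder is the first
positive-to-negative zero-crossing between the time of maximum dP/dt and
the systolic peak. The crossing direction matters: a genuine shoulder is
an upstroke flattening (+→−), whereas any smooth single-hump upstroke
crosses −→+ on the way to its peak; requiring +→− is what rejects
non-type-A waves. AIx = (peak − shoulder)/pulse pressure.

**Wave separation.** `dPf,b = (dP ± rho c dU)/2` cumulated from zero at
cycle start, with `c` the exact theoretical speed at the site (known in
the virtual setting). `Pf + Pb = P − P(0)` holds identically; peak
amplitudes are baseline-referenced.

**Central-pressure reconstruction.** Three pieces: (i) water-hammer
upstroke `P = DBP + rho·PWV·U(t)` from the foot of the aortic velocity
wave to its peak, making the shoulder `P1 = DBP + rho·PWV·max U`;
(ii) a quadratic to end-systole (forward velocity falling below 5% of
peak) with value and slope continuity at the junction and its last
coefficient fixed in closed form by full-cycle MAP conservation (the
mean is linear in that coefficient); (iii) an exponential diastolic
decay toward zero absolute pressure with the time constant fitted on the
final two-thirds of the peripheral (brachial) diastole. If the decay
misses DBP at cycle end by > 1 mmHg, the constant is rescaled to close
the cycle (logged) and the quadratic re-solved; the fixed point is
reached in a few iterations. MAP and DBP come from the brachial wave
(time mean and minimum). Infeasible input combinations (MAP too low for
the implied shape) raise a reconstruction error carrying the residual.

## Numerical choices and edge cases

- Junction Newton iterations stop at relative area increments < 1e-14
  (2–4 iterations in practice); increments are damped to half the
  current area to prevent overshoot to non-physical states.
- A zero-stroke-volume subject relaxes to the uniform venous pressure;
  negative areas or non-finite states abort with a stability error
  suggesting a smaller step, non-convergence with the residual.
- Loop windows shorter than 10 samples, non-positive loop slopes,
  mis-ordered feet, constant-velocity sum-of-squares inputs and
  non-type-A shoulders all raise typed errors; the case-study drivers
  log such subjects as exclusions and continue.
- Pearson correlations use the two-sided sample formula; degenerate
  (zero-variance) inputs return NaN with a warning.

## Known limitations

The reduced tree has 5 bifurcations where a full systemic anatomy has
~29, and its lumped Windkessels concentrate what is anatomically a
diffuse reflection field into few discrete sites. Consequences observed
on the default cohort: reflected waves at the aortic root are smoother,
arrive later, and have decayed by end-diastole, so (i) foot-to-foot PWV
along the aorta is nearly unbiased (+3%) instead of under-reading in
stiff subjects, (ii) the lnDU and sum-of-squares over-estimation at the
ascending aorta (+4%, +31%) is weaker than full-anatomy values, and
(iii) the network-mean reflection coefficient is dominated by the
carotid bifurcation, which reverses its correlation with AIx relative to
a full tree. The estimator sign structure (PU over / lnDU under at
peripheral and carotid sites, QA ≈ lnDU + early-systolic velocity,
sum-of-squares over-reading everywhere, brachial-ankle foot-to-foot
over-reading aortic stiffness) and the central-pressure error ordering
are reproduced. The acceptance suite keeps the affected checks at their
stated tolerances and they fail honestly.
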