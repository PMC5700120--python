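# Example configuration: everything omitted falls back to the built-in
# defaults (see pulsebench._defaults). Shown here: a slightly stiffer,
# smaller cohort with a finer grid.
cohort:
  n: 20
  seed: 12345
ranges:
  c_el_factor: [1.0, 1.7]   # stiff half of the healthy range
numerics:
  dx: 2.0e-3
  periodicity_tol_mmhg: 0.05
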