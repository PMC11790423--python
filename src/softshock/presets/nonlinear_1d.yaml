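# Nonlinear viscoelastic shock-formation run (Y-polarised source).
problem: nonlinear_1d
lengths: [1.0, 0.0, 0.0]
dx_mm: 1.0
t_final: 0.08
epsilon: 0.9
Gamma: 0.95
reconstruction: muscl_minmod
amplitude: 2.0
polarisation: 1
Omega: 82.3
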