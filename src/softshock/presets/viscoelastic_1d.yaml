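# Linear viscoelastic forced run against the FFT-synthesised reference.
problem: viscoelastic_1d
lengths: [1.0, 0.0, 0.0]
dx_mm: 2.0
t_final: 0.18
epsilon: 0.9
Gamma: 0.95
reconstruction: muscl_minmod
amplitude: 1.0
polarisation: 1
linear: true
Omega: 82.3
receivers: [[0.2, 0.0, 0.0]]
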