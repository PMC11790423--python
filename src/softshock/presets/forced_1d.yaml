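# Linear elastic 1D forced problem: point source at X = 0, d'Alembert reference.
problem: forced_1d
lengths: [1.0, 0.0, 0.0]
dx_mm: 2.0
t_final: 0.18
epsilon: 0.9
Gamma: 0.95
reconstruction: none
amplitude: 1.0
polarisation: 1
linear: true
elastic: true
receivers: [[0.25, 0.0, 0.0]]
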