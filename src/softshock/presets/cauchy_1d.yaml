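# Smooth Cauchy problem carrying a right-going shear pulse (order studies).
problem: cauchy_1d
lengths: [1.0, 0.0, 0.0]
dx_mm: 2.0
t_final: 0.18
epsilon: 0.9
Gamma: 0.95
reconstruction: muscl_minmod
amplitude: 1.0
polarisation: 1
linear: true
elastic: true
mesh_ladder_mm: [8.0, 4.0, 2.0, 1.0]
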