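# 3D spherical waves from a truncated Gaussian source (sigma = 18 mm).
problem: sphere_3d
lengths: [0.6, 0.6, 0.6]
dx_mm: 6.0
t_final: 0.18
epsilon: 0.9
Gamma: 0.95
reconstruction: muscl_minmod
amplitude: 0.005
sigma_mm: 18.0
Omega: 82.3
error_window: [0.0, 0.3]
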