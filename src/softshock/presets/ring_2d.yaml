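# 2D telescopic shearing: ring source of radius 0.2 m (focusing study).
problem: ring_2d
lengths: [0.6, 0.6, 0.0]
dx_mm: 2.0
t_final: 0.18
epsilon: 0.9
Gamma: 0.95
reconstruction: muscl_minmod
amplitude: 0.005
radius: 0.2
error_window: [0.0, 0.3]
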