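I (coupled inertia, kg*m^2)
0.45,0.02,0.0,0.03,0.0,0.0,0.0
0.02,0.45,0.0,0.03,0.0,0.0,0.0
0.0,0.0,0.025,0.002,0.0,0.0,0.0
0.03,0.03,0.002,0.08,0.001,0.0,0.0
0.0,0.0,0.0,0.001,0.005,0.0005,0.0
0.0,0.0,0.0,0.0,0.0005,0.004,0.0003
0.0,0.0,0.0,0.0,0.0,0.0003,0.003
D (coupled damping, N*m*s/rad)
0.8,0.04,0.0,0.05,0.0,0.0,0.0
0.04,0.8,0.0,0.05,0.0,0.0,0.0
0.0,0.0,0.3,0.02,0.0,0.0,0.0
0.05,0.05,0.02,0.4,0.01,0.0,0.0
0.0,0.0,0.0,0.01,0.1,0.005,0.0
0.0,0.0,0.0,0.0,0.005,0.06,0.004
0.0,0.0,0.0,0.0,0.0,0.004,0.05
K (coupled stiffness, N*m/rad)
8.0,0.5,0.0,0.6,0.0,0.0,0.0
0.5,8.0,0.0,0.6,0.0,0.0,0.0
0.0,0.0,4.0,0.3,0.0,0.0,0.0
0.6,0.6,0.3,5.0,0.15,0.0,0.0
0.0,0.0,0.0,0.15,2.0,0.1,0.0
0.0,0.0,0.0,0.0,0.1,1.5,0.08
0.0,0.0,0.0,0.0,0.0,0.08,1.2
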