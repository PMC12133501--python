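# Anatomical joint-angle limits (radians) for the 7 arm degrees of freedom.
# Placeholder values in the range of standard goniometric tables; override
# per subject via ExoTremorConfig.  Axis order: q1 SFE, q2 SAA, q3 SEIR,
# q4 EFE, q5 FPS, q6 WFE, q7 WRUD.  Signs follow the package's documented
# rotation-axis convention, not a clinical standard.
q1: [-1.0, 3.0]
q2: [-0.6, 2.9]
q3: [-1.5, 1.5]
q4: [-0.1, 2.5]
q5: [-1.4, 1.4]
q6: [-1.2, 1.2]
q7: [-0.5, 0.6]
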