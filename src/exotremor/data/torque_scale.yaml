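# Maximum Parkinsonian tremor torque per joint axis (N*m).
# Placeholder magnitudes (order 0.1-2 N*m, largest at the shoulder); the
# published per-joint measurements these stand in for are not reprinted
# here, so treat this table as subject-level configuration data.
q1: 2.0
q2: 1.8
q3: 1.0
q4: 0.8
q5: 0.3
q6: 0.2
q7: 0.1
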