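"""The multi-episode suppression protocol (reduced size).

Runs the zero-action and oracle policies over two tremor-axis subsets x
two movements with testing-profile (out-of-distribution) randomization
and prints the per-combination report rows.
"""

import exotremor as xt

trajs = {
    label: xt.generate_synthetic_movement(label, 2.0, 1 / 30, seed=1)
    for label in ("elbow_flexion_extension", "shoulder_flexion_extension")
}
combos = [(3,), (0, 3)]  # q4 alone, q1+q4

for name, policy in [("zero", xt.ZeroPolicy()), ("oracle", xt.OraclePolicy())]:
    report = xt.run_protocol(policy, trajs, n_episodes=3, profile="testing",
                             seed=0, combos=combos)
    cols = ["tremor_axes", "movement", "mean_suppression_pct",
            "mean_occurrence_pct", "mean_torque_suppression_pct"]
    print(f"--- {name} policy")
    print(report[cols].to_string(index=False))
print("-> one row per (axis subset, movement); the full protocol covers all")
print("   15 subsets of {q1..q4} x 4 movements x 100 episodes.")
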