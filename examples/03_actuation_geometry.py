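"""From cable tensions to joint torques.

Loads the default 7-actuator layout, commands the elbow flexor, and
shows the torque it produces about each generalized coordinate.
"""

import numpy as np

import exotremor as xt
from exotremor.dynamics import ArmGeometry

layout = xt.load_layout()
geometry = ArmGeometry()
print(f"layout: {len(layout.actuators)} actuators, "
      f"Fs={layout.Fs:.0f} N (shoulder), Fe={layout.Fe:.0f} N (elbow)")

angles = np.array([0.0, 0.0, 0.0, 0.6, 0.0, 0.0, 0.0])  # mid flexion
forces = np.zeros(7)
forces[5] = 15.0  # elbow flexor at 15 N
tau = xt.total_joint_torques(layout, forces, angles, geometry)
for name, t in zip(xt.JOINT_NAMES, tau):
    print(f"  {name}: {t:+.4f} N*m")
print("-> the elbow flexor torques only q4; no actuators span the wrist,")
print("   so q5-q7 are always zero.  Moment arms change with arm pose.")

# the printed-formula mode, kept for reproducibility, breaks ||F|| = F:
f_unit = xt.force_components((0, 0, 0), (1, 0, 0), 1.0, mode="unit_vector")
f_lit = xt.force_components((0, 0, 0), (1, 0, 0), 1.0, mode="as_printed")
print(f"unit_vector mode force: {f_unit}, |F| = {np.linalg.norm(f_unit):.2f}")
print(f"as_printed  mode force: {f_lit}, |F| = {np.linalg.norm(f_lit):.2f}")
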