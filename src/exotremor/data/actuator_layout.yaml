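# Default soft-exoskeleton cable layout: 7 tension actuators, 5 spanning the
# shoulder (anchored on the torso, pulling on the upper-arm sleeve) and 2
# spanning the elbow (anchored on the upper-arm sleeve, pulling on the
# forearm sleeve).  Coordinates are placeholder anchor positions in metres,
# expressed in each segment's local frame (origin at the proximal joint,
# x forward, y left, z up; the arm hangs along -z in the neutral pose).
# An actuator pulls its endpoint (p2) toward its anchor (p1).
actuators:
  - id: shoulder_flexor
    anchor_segment: torso
    p1: [0.16, 0.02, 0.05]
    endpoint_segment: upper_arm
    p2: [0.035, 0.0, -0.15]
    f_max: 40.0
    joint: shoulder
  - id: shoulder_extensor
    anchor_segment: torso
    p1: [-0.16, 0.0, 0.05]
    endpoint_segment: upper_arm
    p2: [-0.035, 0.0, -0.15]
    f_max: 40.0
    joint: shoulder
  - id: shoulder_abductor
    anchor_segment: torso
    p1: [0.0, -0.12, 0.12]
    endpoint_segment: upper_arm
    p2: [0.0, -0.035, -0.15]
    f_max: 40.0
    joint: shoulder
  - id: shoulder_adductor
    anchor_segment: torso
    p1: [0.0, 0.15, -0.10]
    endpoint_segment: upper_arm
    p2: [0.0, 0.035, -0.15]
    f_max: 40.0
    joint: shoulder
  - id: shoulder_rotator
    anchor_segment: torso
    p1: [0.12, 0.10, 0.0]
    endpoint_segment: upper_arm
    p2: [0.03, -0.04, -0.12]
    f_max: 40.0
    joint: shoulder
  - id: elbow_flexor
    anchor_segment: upper_arm
    p1: [0.04, 0.0, -0.08]
    endpoint_segment: forearm
    p2: [0.03, 0.0, -0.12]
    f_max: 30.0
    joint: elbow
  # The extensor is routed over a posterior standoff bracket at elbow level
  # (10 cm behind the joint) so its moment arm keeps the extension sign
  # across the elbow's flexion range instead of collapsing when the cable
  # line crosses the joint axis.
  - id: elbow_extensor
    anchor_segment: upper_arm
    p1: [-0.10, 0.0, -0.32]
    endpoint_segment: forearm
    p2: [-0.025, 0.0, -0.08]
    f_max: 30.0
    joint: elbow
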