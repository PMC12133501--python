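"""Default configuration data for the arm model and exoskeleton.

The numeric tables shipped under :mod:`exotremor.data` (joint ranges, the
per-axis maximum tremor torque, the coupled inertia/damping/stiffness
matrices and the actuator layout) are documented placeholders on the
anatomical order of magnitude; subject-specific values should be supplied
through the same file formats.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

N_JOINTS = 7

JOINT_NAMES = ("q1", "q2", "q3", "q4", "q5", "q6", "q7")

#: Anatomical meaning of each generalized coordinate.
JOINT_LABELS = {
    "q1": "shoulder flexion/extension (SFE)",
    "q2": "shoulder abduction/adduction (SAA)",
    "q3": "shoulder external/internal rotation (SEIR)",
    "q4": "elbow flexion/extension (EFE)",
    "q5": "forearm pronation/supination (FPS)",
    "q6": "wrist flexion/extension (WFE)",
    "q7": "wrist radial/ulnar deviation (WRUD)",
}

#: Neutral pose (radians): arm hanging with a slight elbow bend.
NEUTRAL_POSE = np.array([0.0, 0.0, 0.0, 0.35, 0.0, 0.0, 0.0])


def _data_path(name: str) -> Path:
    return Path(resources.files("exotremor.data") / name)


def load_joint_ranges(path: str | Path | None = None) -> np.ndarray:
    """Per-joint [lo, hi] limits in radians, shape (7, 2)."""
    path = Path(path) if path is not None else _data_path("joint_ranges.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ranges = np.array([raw[name] for name in JOINT_NAMES], dtype=float)
    if ranges.shape != (N_JOINTS, 2) or np.any(ranges[:, 0] >= ranges[:, 1]):
        raise ValueError(f"invalid joint ranges in {path}")
    return ranges


def load_torque_scale(path: str | Path | None = None) -> np.ndarray:
    """Maximum tremor torque per joint axis (N*m), shape (7,)."""
    path = Path(path) if path is not None else _data_path("torque_scale.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = [name for name in JOINT_NAMES if name not in raw]
    if missing:
        raise KeyError(f"torque scale table missing axes {missing} in {path}")
    scale = np.array([raw[name] for name in JOINT_NAMES], dtype=float)
    if np.any(scale <= 0):
        raise ValueError("torque scale entries must be positive")
    return scale


def default_matrices_path() -> Path:
    return _data_path("anatomical_matrices.csv")


def default_layout_path() -> Path:
    return _data_path("actuator_layout.yaml")
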