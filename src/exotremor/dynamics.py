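"""Coupled 7-DoF displacement dynamics and arm forward kinematics.

The arm's response to tremor and exoskeleton torques is modelled as the
linear second-order system

    I qdd + D qd + K q = tau,

where q is the vector of angular *displacements from the reference
trajectory* on the seven joint axes and I, D, K are the coupled inertia,
damping and stiffness matrices.  Torques required for the intentional
task, the task load and gravity are carried by the reference movement
itself, so only the tremor torque and the exoskeleton torque enter tau.
Off-diagonal entries of I/D/K couple the axes anatomically and are what
makes a tremor driven on one axis propagate to the others.

Each control step is re-initialized from the reference trajectory (not
from the previous simulated pose), which keeps the simulated trajectory
anchored to the voluntary movement; carrying state across steps is
available behind a flag for ablation.

Integration is fixed-substep semi-implicit Euler, which is stable for
stiff linear second-order systems and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .config import N_JOINTS, default_matrices_path, load_joint_ranges

DEFAULT_SUBSTEPS = 20


class DynamicsError(ValueError):
    """Raised for invalid dynamics inputs."""


@dataclass
class AnatomicalMatrices:
    """Coupled inertia (kg*m^2), damping (N*m*s/rad), stiffness (N*m/rad)."""

    I: np.ndarray
    D: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        for name in ("I", "D", "K"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (N_JOINTS, N_JOINTS):
                raise DynamicsError(f"{name} must be 7x7, got {m.shape}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise DynamicsError(f"{name} must be symmetric")
            setattr(self, name, m)
        eigI = np.linalg.eigvalsh(self.I)
        if np.min(eigI) <= 0:
            raise DynamicsError("inertia matrix must be positive definite")
        for name in ("D", "K"):
            if np.min(np.linalg.eigvalsh(getattr(self, name))) < -1e-10:
                raise DynamicsError(f"{name} must be positive semi-definite")

    def scaled(self, sI: float = 1.0, sD: float = 1.0, sK: float = 1.0
               ) -> "AnatomicalMatrices":
        """Uniformly scaled copy (used by dynamics randomization)."""
        return AnatomicalMatrices(self.I * sI, self.D * sD, self.K * sK)


def load_matrices(path: str | Path | None = None) -> AnatomicalMatrices:
    """Read I, D, K from the block CSV format.

    The file holds three blocks, each a one-line header followed by 7 rows
    of 7 comma-separated values, in the order I, D, K.
    """
    path = Path(path) if path is not None else default_matrices_path()
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    blocks = []
    i = 0
    while i < len(lines):
        header = lines[i]
        rows = lines[i + 1 : i + 1 + N_JOINTS]
        if len(rows) < N_JOINTS:
            raise DynamicsError(f"{path}: block {header!r} has fewer than 7 rows")
        try:
            blocks.append(np.array([[float(v) for v in r.split(",")] for r in rows]))
        except ValueError as exc:
            raise DynamicsError(f"{path}: non-numeric entry in block {header!r}") from exc
        i += 1 + N_JOINTS
    if len(blocks) != 3:
        raise DynamicsError(f"{path}: expected 3 matrix blocks, found {len(blocks)}")
    return AnatomicalMatrices(*blocks)


@dataclass
class ArmGeometry:
    """Rigid segment lengths (m) and mass ratios of the arm model."""

    upper_arm_length: float = 0.30
    forearm_length: float = 0.28
    hand_length: float = 0.18
    mass_ratio_upper: float = 0.52
    mass_ratio_forearm: float = 0.33
    mass_ratio_hand: float = 0.15
    shoulder_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("upper_arm_length", "forearm_length", "hand_length"):
            if getattr(self, name) <= 0:
                raise DynamicsError(f"{name} must be positive")
        for name in ("mass_ratio_upper", "mass_ratio_forearm", "mass_ratio_hand"):
            if not 0 < getattr(self, name) < 1:
                raise DynamicsError(f"{name} must be in (0, 1)")

    @property
    def reach(self) -> float:
        return self.upper_arm_length + self.forearm_length + self.hand_length


@dataclass
class DisplacementState:
    """Displacement from the reference pose and its time derivatives."""

    q: np.ndarray
    q_dot: np.ndarray
    q_ddot: np.ndarray

    @classmethod
    def rest(cls) -> "DisplacementState":
        return cls(np.zeros(N_JOINTS), np.zeros(N_JOINTS), np.zeros(N_JOINTS))


def solve_displacement_step(
    matrices: AnatomicalMatrices,
    torque: np.ndarray,
    dt: float,
    init: DisplacementState | None = None,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> DisplacementState:
    """Advance I qdd + D qd + K q = tau by one control step of length dt.

    Semi-implicit Euler with ``n_substeps`` fixed substeps: the torque is
    held constant over the control step.  The default substep count keeps
    the one-step discretization error below 1e-4 rad for torques on the
    tremor scale.
    """
    torque = np.asarray(torque, dtype=float)
    if torque.shape != (N_JOINTS,):
        raise DynamicsError(f"torque must have shape (7,), got {torque.shape}")
    if not np.all(np.isfinite(torque)):
        raise DynamicsError("torque contains non-finite values")
    if dt <= 0:
        raise DynamicsError("dt must be positive")
    if init is None:
        init = DisplacementState.rest()
    q = init.q.astype(float).copy()
    qd = init.q_dot.astype(float).copy()
    h = dt / n_substeps
    I_inv = np.linalg.inv(matrices.I)
    qdd = np.zeros(N_JOINTS)
    for _ in range(n_substeps):
        qdd = I_inv @ (torque - matrices.D @ qd - matrices.K @ q)
        qd = qd + h * qdd
        q = q + h * qd
    return DisplacementState(q, qd, qdd)


def step_from_reference(
    ref_angles_t: np.ndarray,
    tremor_torque_t: np.ndarray,
    exo_torque_t: np.ndarray,
    matrices: AnatomicalMatrices,
    dt: float,
    joint_ranges: np.ndarray | None = None,
    init: DisplacementState | None = None,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> tuple[np.ndarray, DisplacementState, bool]:
    """Simulated joint angles for one control step.

    Solves the displacement system for tau = tremor + exoskeleton torque
    starting from rest (the per-step re-initialization scheme; pass
    ``init`` to carry state instead) and superimposes the displacement on
    the reference pose.  Returns (angles, displacement_state, clamped).
    """
    ref_angles_t = np.asarray(ref_angles_t, dtype=float)
    state = solve_displacement_step(
        matrices,
        np.asarray(tremor_torque_t, dtype=float) + np.asarray(exo_torque_t, dtype=float),
        dt,
        init=init,
        n_substeps=n_substeps,
    )
    angles = ref_angles_t + state.q
    clamped = False
    if joint_ranges is not None:
        lo, hi = joint_ranges[:, 0], joint_ranges[:, 1]
        clipped = np.clip(angles, lo, hi)
        clamped = bool(np.any(clipped != angles))
        angles = clipped
    return angles, state, clamped


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------
# World frame: x forward, y left, z up; the arm hangs along -z in the
# neutral pose.  The shoulder rotation is the intrinsic composition
# R(sfe) R(saa) R(seir) about the axes below (flexion about -y so that
# positive flexion swings the arm forward, abduction about -x so that
# positive abduction swings the right arm away from the torso, axial
# rotation about the humeral -z axis).

_AXES = {
    "sfe": np.array([0.0, -1.0, 0.0]),
    "saa": np.array([-1.0, 0.0, 0.0]),
    "seir": np.array([0.0, 0.0, -1.0]),
    "efe": np.array([0.0, -1.0, 0.0]),
    "fps": np.array([0.0, 0.0, -1.0]),
    "wfe": np.array([0.0, -1.0, 0.0]),
    "wrud": np.array([1.0, 0.0, 0.0]),
}


def _rot(axis_name: str, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(_AXES[axis_name] * angle).as_matrix()


@dataclass
class ArmFrames:
    """World positions (m) and segment orientations of the kinematic chain."""

    shoulder: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    hand: np.ndarray
    R_upper: np.ndarray  # world orientation of the upper-arm frame
    R_forearm: np.ndarray
    R_hand: np.ndarray


def forward_kinematics(angles: np.ndarray, geometry: ArmGeometry) -> ArmFrames:
    """Joint positions and segment frames for a 7-angle configuration."""
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (N_JOINTS,) or not np.all(np.isfinite(angles)):
        raise DynamicsError("angles must be 7 finite values")
    q1, q2, q3, q4, q5, q6, q7 = angles
    shoulder = np.asarray(geometry.shoulder_origin, dtype=float)
    R_upper = _rot("sfe", q1) @ _rot("saa", q2) @ _rot("seir", q3)
    elbow = shoulder + R_upper @ np.array([0.0, 0.0, -geometry.upper_arm_length])
    R_forearm = R_upper @ _rot("efe", q4) @ _rot("fps", q5)
    wrist = elbow + R_forearm @ np.array([0.0, 0.0, -geometry.forearm_length])
    R_hand = R_forearm @ _rot("wfe", q6) @ _rot("wrud", q7)
    hand = wrist + R_hand @ np.array([0.0, 0.0, -geometry.hand_length])
    return ArmFrames(shoulder, elbow, wrist, hand, R_upper, R_forearm, R_hand)


def joint_axis_directions(angles: np.ndarray) -> np.ndarray:
    """World-frame instantaneous rotation axes of q1..q4, shape (4, 3).

    Used to project 3-D shoulder/elbow torque vectors onto the
    generalized coordinates of the displacement system.
    """
    angles = np.asarray(angles, dtype=float)
    q1, q2, q3, q4 = angles[:4]
    R1 = _rot("sfe", q1)
    R12 = R1 @ _rot("saa", q2)
    R_upper = R12 @ _rot("seir", q3)
    return np.stack(
        [
            _AXES["sfe"],
            R1 @ _AXES["saa"],
            R12 @ _AXES["seir"],
            R_upper @ _AXES["efe"],
        ]
    )
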