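"""Soft-exoskeleton actuation: commanded cable forces to joint torques.

Each of the seven tension actuators is a cable between an anchor point P1
(on the torso or a proximal sleeve) and an endpoint P2 (on a distal
sleeve); when commanded it pulls its endpoint toward its anchor.  The
commanded force becomes a 3-D force vector at the endpoint, the force
becomes a torque about the spanned joint through the lever arm from the
joint to the endpoint (tau = r x F), per-joint torques are summed over
actuators, and the summed shoulder/elbow torque vectors are projected
onto the instantaneous q1..q4 rotation axes to produce the length-7
generalized torque that enters the displacement dynamics.  No actuators
span the wrist, so the q5..q7 entries are always zero.

Two force-decomposition modes are provided.  ``unit_vector`` (default)
returns F * (P1-P2)/||P1-P2||, the physically consistent pull of the
endpoint toward the anchor with ||force|| = F.  ``as_printed`` evaluates
the componentwise cosine-of-atan2 decomposition

    Fx = cos(atan2(dy, dx)) F,  Fy = cos(atan2(dx, dy)) F,
    Fz = cos(atan2(dz, dx)) F,   with d = P2 - P1,

which is kept verbatim for reproducibility: note that it makes Fz depend
on dx, so for generic geometry its magnitude differs from F (an x-aligned
cable yields Fz = F).  The regression tests pin this discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .config import N_JOINTS, default_layout_path
from .dynamics import ArmFrames, ArmGeometry, forward_kinematics, joint_axis_directions


class ActuationError(ValueError):
    """Raised for invalid actuator configuration or commands."""


@dataclass
class Actuator:
    """One cable actuator: anchor P1 pulls endpoint P2 toward itself."""

    id: str
    anchor_segment: str  # torso | upper_arm | forearm
    p1: np.ndarray  # local coords on anchor segment (m)
    endpoint_segment: str
    p2: np.ndarray  # local coords on endpoint segment (m)
    f_max: float
    joint: str  # shoulder | elbow

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if self.f_max <= 0:
            raise ActuationError(f"actuator {self.id}: f_max must be positive")
        if self.joint not in ("shoulder", "elbow"):
            raise ActuationError(f"actuator {self.id}: joint must be shoulder|elbow")
        for name, seg in (("anchor", self.anchor_segment),
                          ("endpoint", self.endpoint_segment)):
            if seg not in ("torso", "upper_arm", "forearm"):
                raise ActuationError(
                    f"actuator {self.id}: unknown {name} segment {seg!r}"
                )


@dataclass
class ExoLayout:
    """The full 7-actuator exoskeleton layout."""

    actuators: list[Actuator]

    def __post_init__(self) -> None:
        if len(self.actuators) != N_JOINTS:
            raise ActuationError(
                f"layout must have exactly 7 actuators (R^7 action space), "
                f"got {len(self.actuators)}"
            )

    @property
    def f_max(self) -> np.ndarray:
        return np.array([a.f_max for a in self.actuators])

    @property
    def Fs(self) -> float:
        """Summed maximum force of the shoulder actuators (N)."""
        return float(sum(a.f_max for a in self.actuators if a.joint == "shoulder"))

    @property
    def Fe(self) -> float:
        """Summed maximum force of the elbow actuators (N)."""
        return float(sum(a.f_max for a in self.actuators if a.joint == "elbow"))


def load_layout(path: str | Path | None = None) -> ExoLayout:
    path = Path(path) if path is not None else default_layout_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        actuators = [Actuator(**entry) for entry in raw["actuators"]]
    except (KeyError, TypeError) as exc:
        raise ActuationError(f"malformed actuator layout in {path}: {exc}") from exc
    layout = ExoLayout(actuators)
    if layout.Fs <= 0 or layout.Fe <= 0:
        raise ActuationError("layout needs both shoulder and elbow actuators")
    return layout


def force_components(
    p1: np.ndarray, p2: np.ndarray, force: float, mode: str = "unit_vector"
) -> np.ndarray:
    """3-D force vector exerted at the endpoint P2 for cable tension ``force``."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if force < 0:
        raise ActuationError(f"cable tension must be >= 0, got {force}")
    d = p2 - p1
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ActuationError("actuator endpoints coincide")
    if mode == "unit_vector":
        return -d / norm * force
    if mode == "as_printed":
        return force * np.array(
            [
                np.cos(np.arctan2(d[1], d[0])),
                np.cos(np.arctan2(d[0], d[1])),
                np.cos(np.arctan2(d[2], d[0])),
            ]
        )
    raise ActuationError(f"unknown force mode {mode!r}")


def actuator_torque(
    force: np.ndarray,
    joint_pos: np.ndarray,
    endpoint_pos: np.ndarray,
    lever_sign: float = 1.0,
) -> np.ndarray:
    """Torque about a joint: tau = r x F with r = endpoint - joint.

    ``lever_sign=-1`` flips to the joint-minus-endpoint lever convention.
    """
    force = np.asarray(force, dtype=float)
    r = lever_sign * (np.asarray(endpoint_pos, dtype=float) - np.asarray(joint_pos, dtype=float))
    return np.cross(r, force)


def segment_world_point(
    segment: str, local: np.ndarray, frames: ArmFrames
) -> np.ndarray:
    """Map a segment-local attachment point into world coordinates."""
    local = np.asarray(local, dtype=float)
    if segment == "torso":
        return local  # torso frame == world frame, shoulder at the origin
    if segment == "upper_arm":
        return frames.shoulder + frames.R_upper @ local
    if segment == "forearm":
        return frames.elbow + frames.R_forearm @ local
    raise ActuationError(f"unknown segment {segment!r}")


def actuator_endpoints(
    layout: ExoLayout,
    angles: np.ndarray,
    geometry: ArmGeometry,
    endpoint_shifts: np.ndarray | None = None,
) -> np.ndarray:
    """World positions of all actuator endpoints, shape (7, 3)."""
    frames = forward_kinematics(angles, geometry)
    pts = np.zeros((N_JOINTS, 3))
    for i, act in enumerate(layout.actuators):
        p2 = act.p2 if endpoint_shifts is None else act.p2 + endpoint_shifts[i]
        pts[i] = segment_world_point(act.endpoint_segment, p2, frames)
    return pts


def total_joint_torques(
    layout: ExoLayout,
    commanded_forces: np.ndarray,
    angles: np.ndarray,
    geometry: ArmGeometry,
    endpoint_shifts: np.ndarray | None = None,
    mode: str = "unit_vector",
    strict: bool = False,
    lever_sign: float = 1.0,
) -> np.ndarray:
    """Length-7 generalized torque produced by the commanded cable forces.

    ``endpoint_shifts`` (7, 3) models actuator sliding on the soft sleeve
    (segment-local metres).  Forces outside [0, f_max] are clamped (or
    rejected in ``strict`` mode).
    """
    commanded_forces = np.asarray(commanded_forces, dtype=float)
    if commanded_forces.shape != (N_JOINTS,):
        raise ActuationError("commanded_forces must have 7 entries")
    f_max = layout.f_max
    if strict and np.any((commanded_forces < 0) | (commanded_forces > f_max)):
        raise ActuationError("commanded force outside [0, f_max]")
    forces = np.clip(commanded_forces, 0.0, f_max)

    frames = forward_kinematics(angles, geometry)
    joint_pos = {"shoulder": frames.shoulder, "elbow": frames.elbow}
    torque3 = {"shoulder": np.zeros(3), "elbow": np.zeros(3)}
    for i, act in enumerate(layout.actuators):
        if forces[i] == 0.0:
            continue
        p2_local = act.p2 if endpoint_shifts is None else act.p2 + endpoint_shifts[i]
        p1_world = segment_world_point(act.anchor_segment, act.p1, frames)
        p2_world = segment_world_point(act.endpoint_segment, p2_local, frames)
        fvec = force_components(p1_world, p2_world, forces[i], mode=mode)
        torque3[act.joint] += actuator_torque(
            fvec, joint_pos[act.joint], p2_world, lever_sign=lever_sign
        )

    axes = joint_axis_directions(angles)
    out = np.zeros(N_JOINTS)
    out[0] = axes[0] @ torque3["shoulder"]
    out[1] = axes[1] @ torque3["shoulder"]
    out[2] = axes[2] @ torque3["shoulder"]
    out[3] = axes[3] @ torque3["elbow"]
    return out
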