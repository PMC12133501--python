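"""Reference (voluntary) movement trajectories.

Four single-joint dynamic movements are supported — shoulder
flexion/extension, shoulder abduction/adduction, elbow flexion/extension
and shoulder external rotation — generated as smooth minimum-jerk
out-and-back sweeps of the movement's principal axis while the remaining
axes drift slowly around the neutral pose.  Minimum-jerk profiles are the
standard model of voluntary reaching and keep the voluntary spectrum well
below the 4–12 Hz Parkinsonian tremor band, so voluntary and tremorous
motion remain spectrally separable.

Trajectories round-trip through a plain CSV dialect
(``t,q1,...,q7``; seconds and radians) with a JSON sidecar carrying the
movement label, recording id and sample period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d

from .config import JOINT_NAMES, N_JOINTS, NEUTRAL_POSE, load_joint_ranges

MOVEMENTS = (
    "shoulder_flexion_extension",
    "shoulder_abduction_adduction",
    "elbow_flexion_extension",
    "shoulder_external_rotation",
)

#: Principal joint index (0-based into q1..q7) of each movement.
PRINCIPAL_AXIS = {
    "shoulder_flexion_extension": 0,
    "shoulder_abduction_adduction": 1,
    "elbow_flexion_extension": 3,
    "shoulder_external_rotation": 2,
}

#: Peak sweep amplitude (radians) of the principal axis at amplitude_scale=1.
_SWEEP_AMPLITUDE = {
    "shoulder_flexion_extension": 1.2,
    "shoulder_abduction_adduction": 1.1,
    "elbow_flexion_extension": 1.3,
    "shoulder_external_rotation": 0.9,
}

# Secondary axes: small-amplitude slow drift, an order of magnitude below
# the principal sweep velocity so axis dominance is guaranteed.
_SECONDARY_AMPLITUDE = 0.02  # rad
_SECONDARY_MAX_FREQ = 0.5  # Hz


class TrajectoryError(ValueError):
    """Raised for malformed trajectory inputs."""


@dataclass
class JointTrajectory:
    """Time series of the 7 arm joint angles (radians).

    ``angles`` has shape (n_steps, 7) with columns ordered
    [SFE, SAA, SEIR, EFE, FPS, WFE, WRUD]; ``dt`` is the constant sample
    period in seconds.
    """

    dt: float
    angles: np.ndarray
    movement_label: str
    recording_id: str = "rec0"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.dt <= 0:
            raise TrajectoryError(f"dt must be positive, got {self.dt}")
        if self.angles.ndim != 2 or self.angles.shape[1] != N_JOINTS:
            raise TrajectoryError(
                f"expected 7 joint columns, got shape {self.angles.shape}"
            )
        if len(self.angles) < 3:
            raise TrajectoryError(
                "trajectory needs at least 3 samples (observation history)"
            )
        if not np.all(np.isfinite(self.angles)):
            bad = int(np.argwhere(~np.isfinite(self.angles))[0, 0])
            raise TrajectoryError(f"non-finite angle at row {bad}")

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def duration(self) -> float:
        return (len(self.angles) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.angles)) * self.dt


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(u) on u in [0, 1], s(0)=0, s(1)=1."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _min_jerk_pulse(u: np.ndarray) -> np.ndarray:
    """Out-and-back profile: 0 -> 1 -> 0 over u in [0, 1], C2-smooth."""
    return np.where(u <= 0.5, _min_jerk(2 * u), _min_jerk(2 - 2 * u))


def generate_synthetic_movement(
    movement_label: str,
    duration_s: float = 4.0,
    dt: float = 1 / 30,
    amplitude_scale: float = 1.0,
    seed: int = 0,
    joint_ranges: np.ndarray | None = None,
) -> JointTrajectory:
    """Generate a smooth single-joint reference movement.

    The principal axis of ``movement_label`` sweeps a minimum-jerk
    out-and-back arc from the neutral pose; the six other axes hold small,
    slowly varying values.  Deterministic given ``seed``.
    """
    if movement_label not in MOVEMENTS:
        raise TrajectoryError(
            f"unknown movement label {movement_label!r}; expected one of {MOVEMENTS}"
        )
    if dt <= 0:
        raise TrajectoryError(f"dt must be positive, got {dt}")
    n = int(round(duration_s / dt)) + 1
    if n < 3:
        raise TrajectoryError("duration_s/dt must allow at least 3 samples")
    if joint_ranges is None:
        joint_ranges = load_joint_ranges()

    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    u = t / t[-1]
    angles = np.tile(NEUTRAL_POSE, (n, 1))

    axis = PRINCIPAL_AXIS[movement_label]
    sweep = _SWEEP_AMPLITUDE[movement_label] * float(amplitude_scale)
    lo, hi = joint_ranges[axis]
    peak = np.clip(NEUTRAL_POSE[axis] + sweep, lo, hi)
    angles[:, axis] = NEUTRAL_POSE[axis] + (peak - NEUTRAL_POSE[axis]) * _min_jerk_pulse(u)

    # sin^2 envelope keeps secondary axes exactly at neutral at both ends.
    envelope = np.sin(np.pi * u) ** 2
    for j in range(N_JOINTS):
        if j == axis:
            continue
        freq = rng.uniform(0.2, _SECONDARY_MAX_FREQ)
        phase = rng.uniform(0, 2 * np.pi)
        wobble = _SECONDARY_AMPLITUDE * float(amplitude_scale) * np.sin(
            2 * np.pi * freq * t + phase
        )
        angles[:, j] = NEUTRAL_POSE[j] + envelope * wobble

    angles = np.clip(angles, joint_ranges[:, 0], joint_ranges[:, 1])
    return JointTrajectory(
        dt=dt,
        angles=angles,
        movement_label=movement_label,
        recording_id=f"seed{seed}",
    )


def save_trajectory(traj: JointTrajectory, path: str | Path) -> Path:
    """Write trajectory CSV (``t,q1..q7``) plus a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(traj.angles, columns=list(JOINT_NAMES))
    frame.insert(0, "t", traj.times)
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "movement_label": traj.movement_label,
                "recording_id": traj.recording_id,
                "dt": traj.dt,
            },
            indent=2,
        )
    )
    return path


def load_trajectory(path: str | Path) -> JointTrajectory:
    """Read a trajectory CSV written by :func:`save_trajectory`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryError(f"{path} is empty") from exc
    expected = ["t", *JOINT_NAMES]
    if list(frame.columns) != expected:
        n_q = sum(c.startswith("q") for c in frame.columns)
        raise TrajectoryError(
            f"{path}: expected 7 joint columns {expected}, got {list(frame.columns)}"
            f" ({n_q} joint columns)"
        )
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise TrajectoryError(f"{path}: NaN value at row {row}")
    tcol = frame["t"].to_numpy()
    dts = np.diff(tcol)
    if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6)):
        row = int(np.argmax((dts <= 0) | ~np.isclose(dts, dts[0], rtol=1e-6))) + 1
        raise TrajectoryError(f"{path}: time column not uniformly increasing at row {row}")
    meta = {"movement_label": MOVEMENTS[0], "recording_id": path.stem, "dt": None}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    dt = meta["dt"] if meta["dt"] is not None else float(dts[0])
    return JointTrajectory(
        dt=float(dt),
        angles=frame[list(JOINT_NAMES)].to_numpy(),
        movement_label=meta["movement_label"],
        recording_id=meta["recording_id"],
    )


def resample(traj: JointTrajectory, new_dt: float) -> JointTrajectory:
    """Resample onto a new uniform grid (cubic interpolation, endpoints kept).

    Reconciles an arbitrary recording rate with the 30–40 Hz control rate
    of the exoskeleton actuators.
    """
    if new_dt <= 0:
        raise TrajectoryError(f"new_dt must be positive, got {new_dt}")
    if new_dt > traj.duration:
        raise TrajectoryError(
            f"new_dt={new_dt} exceeds trajectory duration {traj.duration}"
        )
    if abs(new_dt - traj.dt) < 1e-15:
        return JointTrajectory(
            traj.dt, traj.angles.copy(), traj.movement_label, traj.recording_id
        )
    t_old = traj.times
    n_new = int(np.floor(traj.duration / new_dt)) + 1
    t_new = np.arange(n_new) * new_dt
    if len(t_old) >= 4:
        interp = CubicSpline(t_old, traj.angles, axis=0)
    else:
        interp = interp1d(t_old, traj.angles, axis=0)
    return JointTrajectory(
        new_dt, interp(t_new), traj.movement_label, traj.recording_id
    )


def movement_library(
    seeds: tuple[int, int] = (0, 1),
    duration_s: float = 4.0,
    dt: float = 1 / 30,
    amplitude_scale: float = 1.0,
) -> dict[str, list[JointTrajectory]]:
    """Two recordings of each of the four movements, keyed by label.

    Two seed-varied re-generations per movement emulate distinct recording
    sessions of the same movement pattern.
    """
    return {
        label: [
            generate_synthetic_movement(label, duration_s, dt, amplitude_scale, seed)
            for seed in seeds
        ]
        for label in MOVEMENTS
    }
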