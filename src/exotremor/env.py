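"""Gym-style tremor-suppression environment.

One environment instance wraps one reference movement.  Each episode
samples dynamics-randomization parameters and a tremor; each control step
maps the agent's action in [-1, 1]^7 to cable forces, converts them to
joint torques through the actuator geometry, advances the coupled
displacement dynamics re-initialized from the reference trajectory, and
returns the 80-dimensional observation together with the five-term
shaped reward.

The observation concatenates normalized histories
``{F_{t-2:t}, tau_{t-2:t}, p^a_{t-1:t}, p^j_{t-1:t}}``: actuator forces,
tremor torques, actuator endpoint positions and joint positions.  The
force/position histories end at the last completed control interval,
while the tremor-torque history ends at the torque measured for the
interval the next action acts in — the controller reacts to the tremor
it currently senses rather than predicting it one step ahead.  The
exact per-block history depths that total 80 dimensions are configurable
(the shipped default uses a 2-step force history over 7 actuators, a
3-step tremor-torque history over the four trainable axes q1..q4, a
2-step endpoint history over 7 actuators in 3-D, and a 2-step history of
the elbow and wrist positions: 14 + 12 + 42 + 12 = 80).

API: ``reset(seed) -> (obs, info)`` and
``step(action) -> (obs, reward, terminated, truncated, info)``, with the
full :class:`StepRecord` for the step in ``info["record"]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuation import ExoLayout, actuator_endpoints, load_layout, total_joint_torques
from .config import N_JOINTS, load_joint_ranges, load_torque_scale
from .dynamics import (
    AnatomicalMatrices,
    ArmGeometry,
    forward_kinematics,
    load_matrices,
    step_from_reference,
)
from .motion import JointTrajectory
from .rewards import RewardBreakdown, RewardConfig, total_reward
from .tremor import TremorSpec, generate_tremor_series, sample_tremor_spec

#: Trainable tremor axes: the three shoulder axes and elbow flexion/extension.
TRAINABLE_AXES = (0, 1, 2, 3)

#: History warm-up: the deepest observation history block spans 3 steps.
HISTORY_WARMUP = 3


@dataclass(frozen=True)
class RandomizationProfile:
    """Per-episode uniform sampling ranges for dynamics randomization."""

    name: str
    matrix_scale: tuple[float, float]
    actuator_precision: tuple[float, float]
    endpoint_shift_cm: tuple[float, float]
    f1: tuple[float, float]
    f2: tuple[float, float]
    amplitude: tuple[float, float]


#: Training and (wider, out-of-distribution) testing randomization ranges.
RANDOMIZATION_PROFILES = {
    "training": RandomizationProfile(
        name="training",
        matrix_scale=(0.9, 1.1),
        actuator_precision=(0.97, 1.03),
        endpoint_shift_cm=(0.0, 2.0),
        f1=(4.0, 6.0),
        f2=(8.0, 12.0),
        amplitude=(0.1, 1.0),
    ),
    "testing": RandomizationProfile(
        name="testing",
        matrix_scale=(0.875, 1.125),
        actuator_precision=(0.96, 1.04),
        endpoint_shift_cm=(0.0, 2.5),
        f1=(3.75, 6.25),
        f2=(7.5, 12.5),
        amplitude=(0.05, 1.05),
    ),
}


@dataclass
class ObservationConfig:
    """History depths of the four observation blocks."""

    force_steps: int = 2
    torque_steps: int = 3
    torque_axes: tuple[int, ...] = TRAINABLE_AXES
    endpoint_steps: int = 2
    joint_steps: int = 2
    n_tracked_joints: int = 2  # elbow and wrist

    @property
    def dim(self) -> int:
        return (
            N_JOINTS * self.force_steps
            + len(self.torque_axes) * self.torque_steps
            + N_JOINTS * 3 * self.endpoint_steps
            + self.n_tracked_joints * 3 * self.joint_steps
        )


@dataclass
class EnvConfig:
    dt: float = 1 / 30
    n_substeps: int = 20
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    reward: RewardConfig = field(default_factory=RewardConfig)
    noise_sigma: float = 0.1
    carry_state: bool = False  # ablation: carry q/qd across control steps
    force_mode: str = "unit_vector"
    randomize_endpoint_sign: bool = True


@dataclass
class StepRecord:
    """Full log of one environment step."""

    t: int
    ref_angles: np.ndarray
    tremor_only_angles: np.ndarray
    suppressed_angles: np.ndarray
    tau_t: np.ndarray  # tremor torque (7,)
    tau_o: np.ndarray  # exoskeleton torque (7,)
    tau_e: np.ndarray  # residual torque on affected axes after the exoskeleton
    tau_u: np.ndarray  # exoskeleton torque on non-affected axes
    forces: np.ndarray
    reward: RewardBreakdown
    clamped: bool


@dataclass
class EpisodeRandomization:
    """The randomization draw in force for one episode."""

    matrix_scales: np.ndarray  # (3,) multipliers of I, D, K
    precision: np.ndarray  # (7,) commanded->actual force factors
    endpoint_shift_m: np.ndarray  # (7, 3) local-frame endpoint shifts
    endpoint_shift_magnitude_m: np.ndarray  # (7,)
    tremor: TremorSpec


class TremorSuppressionEnv:
    """One reference movement + generated tremor + exoskeleton, as an MDP."""

    def __init__(
        self,
        trajectory: JointTrajectory,
        tremor_axes: tuple[int, ...],
        profile: str | RandomizationProfile = "training",
        config: EnvConfig | None = None,
        layout: ExoLayout | None = None,
        matrices: AnatomicalMatrices | None = None,
        geometry: ArmGeometry | None = None,
        torque_scale: np.ndarray | None = None,
        joint_ranges: np.ndarray | None = None,
        seed: int | None = None,
    ) -> None:
        tremor_axes = tuple(sorted(set(int(a) for a in tremor_axes)))
        if not tremor_axes or any(a not in TRAINABLE_AXES for a in tremor_axes):
            raise ValueError(
                f"tremor_axes must be a non-empty subset of q1..q4 "
                f"(indices {TRAINABLE_AXES}), got {tremor_axes}"
            )
        self.trajectory = trajectory
        self.tremor_axes = tremor_axes
        self.profile = (
            RANDOMIZATION_PROFILES[profile] if isinstance(profile, str) else profile
        )
        self.config = config or EnvConfig()
        self.layout = layout or load_layout()
        self.base_matrices = matrices or load_matrices()
        self.geometry = geometry or ArmGeometry()
        self.torque_scale = (
            torque_scale if torque_scale is not None else load_torque_scale()
        )
        self.joint_ranges = (
            joint_ranges if joint_ranges is not None else load_joint_ranges()
        )
        self._rng = np.random.default_rng(seed)
        self.observation_dim = self.config.observation.dim
        self.action_dim = N_JOINTS
        self._episode = None

    # -- episode lifecycle ---------------------------------------------------

    def _sample_randomization(self, rng: np.random.Generator) -> EpisodeRandomization:
        prof = self.profile
        matrix_scales = rng.uniform(*prof.matrix_scale, size=3)
        precision = rng.uniform(*prof.actuator_precision, size=N_JOINTS)
        magnitude = rng.uniform(*prof.endpoint_shift_cm, size=N_JOINTS) / 100.0
        shifts = np.zeros((N_JOINTS, 3))
        axes = rng.integers(0, 3, size=N_JOINTS)
        signs = (
            rng.choice([-1.0, 1.0], size=N_JOINTS)
            if self.config.randomize_endpoint_sign
            else np.ones(N_JOINTS)
        )
        shifts[np.arange(N_JOINTS), axes] = signs * magnitude
        tremor = sample_tremor_spec(
            {"f1": prof.f1, "f2": prof.f2, "amplitude": prof.amplitude},
            self.tremor_axes,
            rng,
            noise_sigma=self.config.noise_sigma,
        )
        return EpisodeRandomization(
            matrix_scales, precision, shifts, magnitude, tremor
        )

    def reset(self, seed: int | None = None) -> tuple[np.ndarray, dict]:
        """Sample a new randomization draw and tremor; zero the force history."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        rng = self._rng
        rand = self._sample_randomization(rng)
        self.randomization = rand
        self.matrices = self.base_matrices.scaled(*rand.matrix_scales)
        n = len(self.trajectory)
        self.tremor_series = generate_tremor_series(
            rand.tremor, n, self.config.dt, self.torque_scale
        )
        self._t = HISTORY_WARMUP - 1  # pointer to the last observed frame
        self._force_hist = np.zeros((3, N_JOINTS))
        # The tremor-torque history ends at the torque acting during the
        # *next* control interval: the controller reads the current
        # interval's measured tremor before its force is applied.
        self._torque_hist = np.array(
            [self.tremor_series.torques[t] for t in range(self._t - 1, self._t + 2)]
        )
        self._endpoint_hist = np.array(
            [
                actuator_endpoints(
                    self.layout,
                    self.trajectory.angles[t],
                    self.geometry,
                    rand.endpoint_shift_m,
                )
                for t in range(self._t - 1, self._t + 1)
            ]
        )
        self._joint_hist = np.array(
            [
                self._tracked_joint_positions(self.trajectory.angles[t])
                for t in range(self._t - 1, self._t + 1)
            ]
        )
        self._carry = None
        self._episode = True
        return self._build_observation(), {"randomization": rand}

    def _tracked_joint_positions(self, angles: np.ndarray) -> np.ndarray:
        frames = forward_kinematics(angles, self.geometry)
        return np.stack([frames.elbow, frames.wrist])

    # -- observation ---------------------------------------------------------

    def _build_observation(self) -> np.ndarray:
        cfg = self.config.observation
        reach = self.geometry.reach
        f_norm = self._force_hist[-cfg.force_steps :] / self.layout.f_max
        tau_norm = (
            self._torque_hist[-cfg.torque_steps :][:, list(cfg.torque_axes)]
            / self.torque_scale[list(cfg.torque_axes)]
        )
        p_a = self._endpoint_hist[-cfg.endpoint_steps :] / reach
        p_j = self._joint_hist[-cfg.joint_steps :] / reach
        obs = np.concatenate(
            [f_norm.ravel(), tau_norm.ravel(), p_a.ravel(), p_j.ravel()]
        )
        return np.clip(obs, -1.0, 1.0)

    # -- transition ----------------------------------------------------------

    def action_to_forces(self, action: np.ndarray) -> np.ndarray:
        """Affine map from [-1, 1]^7 to commanded forces, with the sampled
        actuator-precision factor applied."""
        action = np.asarray(action, dtype=float)
        if action.shape != (N_JOINTS,):
            raise ValueError(f"action must have 7 entries, got {action.shape}")
        if not np.all(np.isfinite(action)):
            raise ValueError("action contains non-finite values")
        commanded = (np.clip(action, -1.0, 1.0) + 1.0) / 2.0 * self.layout.f_max
        return np.clip(commanded * self.randomization.precision, 0.0, self.layout.f_max)

    def step(
        self,
        action: np.ndarray,
        exo_torque_override: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float, bool, bool, dict]:
        if self._episode is None:
            raise RuntimeError("call reset() before step()")
        cfg = self.config
        t = self._t + 1
        ref = self.trajectory.angles[t]
        tau_t = self.tremor_series.torques[t]

        if exo_torque_override is not None:
            forces = np.zeros(N_JOINTS)
            tau_o = np.asarray(exo_torque_override, dtype=float)
        else:
            forces = self.action_to_forces(action)
            tau_o = total_joint_torques(
                self.layout,
                forces,
                ref,
                self.geometry,
                endpoint_shifts=self.randomization.endpoint_shift_m,
                mode=cfg.force_mode,
            )

        init = self._carry if cfg.carry_state else None
        suppressed, state, clamped = step_from_reference(
            ref, tau_t, tau_o, self.matrices, cfg.dt,
            joint_ranges=self.joint_ranges, init=init, n_substeps=cfg.n_substeps,
        )
        tremor_only, _, _ = step_from_reference(
            ref, tau_t, np.zeros(N_JOINTS), self.matrices, cfg.dt,
            joint_ranges=self.joint_ranges, init=None, n_substeps=cfg.n_substeps,
        )
        if cfg.carry_state:
            self._carry = state

        affected = list(self.tremor_axes)
        unaffected = [a for a in range(N_JOINTS) if a not in affected]
        tau_e = tau_t[affected] + tau_o[affected]
        tau_u = tau_o[unaffected]

        self._force_hist = np.roll(self._force_hist, -1, axis=0)
        self._force_hist[-1] = forces
        breakdown = total_reward(
            n_axes=len(affected),
            tau_e=tau_e,
            tau_t=tau_t[affected],
            forces=forces,
            force_history=self._force_hist,
            tau_u=tau_u,
            Fe=self.layout.Fe,
            Fs=self.layout.Fs,
            config=cfg.reward,
        )

        self._torque_hist = np.roll(self._torque_hist, -1, axis=0)
        t_next = min(t + 1, len(self.trajectory) - 1)
        self._torque_hist[-1] = self.tremor_series.torques[t_next]
        self._endpoint_hist = np.roll(self._endpoint_hist, -1, axis=0)
        self._endpoint_hist[-1] = actuator_endpoints(
            self.layout, suppressed, self.geometry,
            self.randomization.endpoint_shift_m,
        )
        self._joint_hist = np.roll(self._joint_hist, -1, axis=0)
        self._joint_hist[-1] = self._tracked_joint_positions(suppressed)

        self._t = t
        terminated = t >= len(self.trajectory) - 1
        record = StepRecord(
            t=t,
            ref_angles=ref.copy(),
            tremor_only_angles=tremor_only,
            suppressed_angles=suppressed,
            tau_t=tau_t.copy(),
            tau_o=tau_o,
            tau_e=tau_e,
            tau_u=tau_u,
            forces=forces,
            reward=breakdown,
            clamped=clamped,
        )
        return (
            self._build_observation(),
            breakdown.total,
            terminated,
            False,
            {"record": record},
        )

    @property
    def episode_length(self) -> int:
        """Steps per episode: trajectory length minus the history warm-up."""
        return len(self.trajectory) - HISTORY_WARMUP


def make_env_set(
    trajectories: dict[str, JointTrajectory] | dict[str, list[JointTrajectory]],
    tremor_axes: tuple[int, ...],
    profile: str = "training",
    config: EnvConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> dict[str, TremorSuppressionEnv]:
    """One environment per reference movement (the parallel training set)."""
    envs = {}
    for i, (label, traj) in enumerate(sorted(trajectories.items())):
        if isinstance(traj, list):
            traj = traj[0]
        envs[label] = TremorSuppressionEnv(
            traj, tremor_axes, profile=profile, config=config,
            seed=seed + 1000 * i, **kwargs,
        )
    return envs
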