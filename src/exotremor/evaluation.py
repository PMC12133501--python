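"""Suppression metrics and the multi-episode evaluation protocol.

Amplitude suppression is the RMS-ratio reduction of tremor-induced
angular deviation from the reference trajectory:

    100 * (1 - RMS(suppressed - ref) / RMS(tremor_only - ref))

over the tremor-affected axes — 100% when the suppressed trajectory
equals the reference, 0% when the exoskeleton changes nothing, negative
when it amplifies the tremor.  Time-resolved curves use the same ratio
on a sliding window of one first-harmonic tremor period.  Occurrence is
the percentage of steps where the tremor was reduced without disrupting
the voluntary trajectory: deviation on the affected axes strictly below
the tremor-only deviation while every unaffected axis stays within a
tolerance of the reference.

The full protocol sweeps all 15 non-empty subsets of the four trainable
tremor axes {q1..q4} crossed with the four reference movements, with
out-of-distribution (testing-profile) dynamics randomization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import N_JOINTS
from .env import TRAINABLE_AXES, EnvConfig, StepRecord, TremorSuppressionEnv
from .motion import JointTrajectory

#: Numerical floor below which a deviation counts as "no tremor left".
_DEV_TOL = 1e-12


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------


class ZeroPolicy:
    """No intervention: all actuator forces at their minimum (zero)."""

    provides_torque = False

    def __call__(self, obs: np.ndarray, env: TremorSuppressionEnv) -> np.ndarray:
        return -np.ones(env.action_dim)


class OraclePolicy:
    """Perfect-cancellation upper bound: commands tau_O = -tau_T directly.

    Reads the tremor torque from the simulator and bypasses the actuator
    model, so it is a sanity anchor for the metrics, not a realizable
    controller.
    """

    provides_torque = True

    def torque(self, env: TremorSuppressionEnv) -> np.ndarray:
        return -env.tremor_series.torques[env._t + 1]


class FeedforwardPolicy:
    """Model-based inverse-actuation baseline.

    Solves, by non-negative least squares on the nominal (unrandomized)
    actuation map, for the cable forces whose joint torques best cancel
    the currently sensed tremor torque.  Unlike :class:`OraclePolicy`
    this acts through the real actuator path, so per-episode actuator
    precision and endpoint-shift randomization degrade it — it marks what
    a perfectly identified feedforward model could do.
    """

    provides_torque = False

    def __call__(self, obs: np.ndarray, env: TremorSuppressionEnv) -> np.ndarray:
        from scipy.optimize import nnls

        from .actuation import total_joint_torques

        t = env._t + 1
        ref = env.trajectory.angles[t]
        tau_t = env.tremor_series.torques[t]
        f_max = env.layout.f_max
        # per-Newton torque columns of each actuator at the nominal geometry
        A = np.zeros((4, 7))
        for i in range(7):
            unit = np.zeros(7)
            unit[i] = 1.0
            A[:, i] = total_joint_torques(
                env.layout, unit, ref, env.geometry, mode=env.config.force_mode
            )[:4]
        forces, _ = nnls(A, -tau_t[:4])
        forces = np.minimum(forces, f_max)
        return 2.0 * forces / f_max - 1.0


class AgentPolicy:
    """Wraps trained TD7 networks (optionally the checkpoint snapshot)."""

    provides_torque = False

    def __init__(self, nets, use_checkpoint: bool = True) -> None:
        self.nets = nets
        self.use_checkpoint = use_checkpoint

    def __call__(self, obs: np.ndarray, env: TremorSuppressionEnv) -> np.ndarray:
        return self.nets.act(obs, use_checkpoint=self.use_checkpoint)


# ---------------------------------------------------------------------------
# Episode rollout
# ---------------------------------------------------------------------------


@dataclass
class EpisodeResult:
    """Stacked per-step logs of one evaluated episode."""

    records: list[StepRecord]
    total_reward: float
    f1: float

    @property
    def ref(self) -> np.ndarray:
        return np.stack([r.ref_angles for r in self.records])

    @property
    def tremor_only(self) -> np.ndarray:
        return np.stack([r.tremor_only_angles for r in self.records])

    @property
    def suppressed(self) -> np.ndarray:
        return np.stack([r.suppressed_angles for r in self.records])

    @property
    def tau_t(self) -> np.ndarray:
        return np.stack([r.tau_t for r in self.records])

    @property
    def tau_e_full(self) -> np.ndarray:
        return np.stack([r.tau_t + r.tau_o for r in self.records])

    def to_hdf5(self, path) -> None:
        """Write the episode's step arrays to an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("ref_angles", data=self.ref)
            fh.create_dataset("tremor_only_angles", data=self.tremor_only)
            fh.create_dataset("suppressed_angles", data=self.suppressed)
            fh.create_dataset("tau_t", data=self.tau_t)
            fh.create_dataset("tau_o", data=np.stack([r.tau_o for r in self.records]))
            fh.create_dataset("forces", data=np.stack([r.forces for r in self.records]))
            fh.create_dataset(
                "reward", data=np.array([r.reward.total for r in self.records])
            )
            fh.attrs["f1_hz"] = self.f1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"t": r.t, "reward": r.reward.total, "clamped": r.clamped}
            for j in range(N_JOINTS):
                row[f"ref_q{j+1}"] = r.ref_angles[j]
                row[f"sup_q{j+1}"] = r.suppressed_angles[j]
                row[f"trem_q{j+1}"] = r.tremor_only_angles[j]
                row[f"tau_t{j+1}"] = r.tau_t[j]
                row[f"tau_o{j+1}"] = r.tau_o[j]
                row[f"force{j+1}"] = r.forces[j]
            rows.append(row)
        return pd.DataFrame(rows)


def run_episode(
    env: TremorSuppressionEnv, policy, seed: int | None = None
) -> EpisodeResult:
    obs, _ = env.reset(seed=seed)
    records, total, done = [], 0.0, False
    while not done:
        if getattr(policy, "provides_torque", False):
            tau = policy.torque(env)
            obs, r, done, _, info = env.step(
                np.zeros(env.action_dim), exo_torque_override=tau
            )
        else:
            obs, r, done, _, info = env.step(policy(obs, env))
        records.append(info["record"])
        total += r
    return EpisodeResult(records, total, f1=env.randomization.tremor.f1)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def amplitude_suppression(
    ref: np.ndarray,
    tremor_only: np.ndarray,
    suppressed: np.ndarray,
    affected_axes: tuple[int, ...],
) -> float:
    """Episode-level RMS-ratio amplitude suppression, in percent (<= 100)."""
    axes = list(affected_axes)
    dev_s = np.asarray(suppressed)[:, axes] - np.asarray(ref)[:, axes]
    dev_t = np.asarray(tremor_only)[:, axes] - np.asarray(ref)[:, axes]
    rms_t = np.sqrt(np.mean(dev_t**2))
    if rms_t < _DEV_TOL:
        return 100.0 if np.sqrt(np.mean(dev_s**2)) < _DEV_TOL else 0.0
    return 100.0 * (1.0 - np.sqrt(np.mean(dev_s**2)) / rms_t)


def suppression_curve(
    ref: np.ndarray,
    tremor_only: np.ndarray,
    suppressed: np.ndarray,
    affected_axes: tuple[int, ...],
    window: int,
) -> np.ndarray:
    """Per-step amplitude suppression on a sliding window (one tremor period).

    Entry i covers steps [i, i + window); length is n - window + 1.
    """
    axes = list(affected_axes)
    dev_s = np.asarray(suppressed)[:, axes] - np.asarray(ref)[:, axes]
    dev_t = np.asarray(tremor_only)[:, axes] - np.asarray(ref)[:, axes]
    n = len(dev_s)
    window = max(1, min(window, n))
    kernel = np.ones(window) / window
    ms_s = np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="valid"), 0, dev_s**2
    ).mean(axis=1)
    ms_t = np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="valid"), 0, dev_t**2
    ).mean(axis=1)
    out = np.full(len(ms_s), 100.0)
    nonzero = ms_t >= _DEV_TOL**2
    out[nonzero] = 100.0 * (1.0 - np.sqrt(ms_s[nonzero] / ms_t[nonzero]))
    out[~nonzero & (ms_s >= _DEV_TOL**2)] = 0.0
    return out


def torque_suppression(
    tau_t: np.ndarray, tau_e: np.ndarray, affected_axes: tuple[int, ...]
) -> float:
    """Percent reduction in RMS tremor torque on the affected axes."""
    axes = list(affected_axes)
    rms_t = np.sqrt(np.mean(np.asarray(tau_t)[:, axes] ** 2))
    if rms_t < _DEV_TOL:
        return 0.0
    rms_e = np.sqrt(np.mean(np.asarray(tau_e)[:, axes] ** 2))
    return 100.0 * (1.0 - rms_e / rms_t)


def occurrence(
    ref: np.ndarray,
    tremor_only: np.ndarray,
    suppressed: np.ndarray,
    affected_axes: tuple[int, ...],
    epsilon: float | None = None,
) -> float:
    """Percent of steps with tremor reduced and voluntary motion intact.

    A step counts when the affected-axis deviation is strictly below the
    tremor-only deviation (or both are numerically zero) AND the largest
    unaffected-axis deviation stays below ``epsilon`` (default: 5% of the
    movement's overall angular range).
    """
    ref = np.asarray(ref)
    axes = list(affected_axes)
    other = [a for a in range(N_JOINTS) if a not in axes]
    if epsilon is None:
        span = float(np.ptp(ref)) or 1.0
        epsilon = 0.05 * span
    dev_s = np.sqrt(np.mean((np.asarray(suppressed)[:, axes] - ref[:, axes]) ** 2, axis=1))
    dev_t = np.sqrt(np.mean((np.asarray(tremor_only)[:, axes] - ref[:, axes]) ** 2, axis=1))
    reduced = (dev_s < dev_t) | ((dev_t < _DEV_TOL) & (dev_s < _DEV_TOL))
    if other:
        dev_u = np.max(
            np.abs(np.asarray(suppressed)[:, other] - ref[:, other]), axis=1
        )
        intact = dev_u < epsilon
    else:
        intact = np.ones(len(ref), dtype=bool)
    return 100.0 * float(np.mean(reduced & intact))


def episode_metrics(
    result: EpisodeResult, affected_axes: tuple[int, ...], dt: float
) -> dict[str, float]:
    """All episode-level metrics plus the peak of the windowed curve."""
    ref, trem, sup = result.ref, result.tremor_only, result.suppressed
    window = max(1, int(round(1.0 / (result.f1 * dt))))
    curve = suppression_curve(ref, trem, sup, affected_axes, window)
    return {
        "amplitude_suppression_pct": amplitude_suppression(ref, trem, sup, affected_axes),
        "peak_windowed_suppression_pct": float(np.max(curve)),
        "occurrence_pct": occurrence(ref, trem, sup, affected_axes),
        "torque_suppression_pct": torque_suppression(
            result.tau_t, result.tau_e_full, affected_axes
        ),
        "mean_reward": result.total_reward / len(result.records),
    }


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------


def tremor_axis_combinations() -> list[tuple[int, ...]]:
    """All 15 non-empty subsets of the trainable axes {q1, q2, q3, q4}."""
    combos = []
    for k in range(1, len(TRAINABLE_AXES) + 1):
        combos.extend(combinations(TRAINABLE_AXES, k))
    return combos


def run_protocol(
    policy,
    trajectories: dict[str, JointTrajectory],
    n_episodes: int = 100,
    profile: str = "testing",
    seed: int = 0,
    config: EnvConfig | None = None,
    combos: list[tuple[int, ...]] | None = None,
    **env_kwargs,
) -> pd.DataFrame:
    """Evaluate a policy over tremor-axis combinations x movements.

    Returns one row per (combination, movement) with mean/median/max
    amplitude suppression, occurrence and torque suppression over
    ``n_episodes`` episodes; axis-first and episode-first averaging of
    the suppression are both reported (``*_axisfirst`` aggregates per
    axis before averaging across episodes).
    """
    combos = combos if combos is not None else tremor_axis_combinations()
    cfg = config or EnvConfig()
    rows = []
    for ci, axes in enumerate(combos):
        for mi, (label, traj) in enumerate(sorted(trajectories.items())):
            env = TremorSuppressionEnv(
                traj, axes, profile=profile, config=cfg, **env_kwargs
            )
            sups, occs, tsups, peaks, per_axis = [], [], [], [], []
            for ep in range(n_episodes):
                ep_seed = seed + 100_000 * ci + 1000 * mi + ep
                result = run_episode(env, policy, seed=ep_seed)
                m = episode_metrics(result, axes, cfg.dt)
                sups.append(m["amplitude_suppression_pct"])
                occs.append(m["occurrence_pct"])
                tsups.append(m["torque_suppression_pct"])
                peaks.append(m["peak_windowed_suppression_pct"])
                per_axis.append(
                    [
                        amplitude_suppression(
                            result.ref, result.tremor_only, result.suppressed, (a,)
                        )
                        for a in axes
                    ]
                )
            rows.append(
                {
                    "tremor_axes": "+".join(f"q{a+1}" for a in axes),
                    "movement": label,
                    "n_episodes": n_episodes,
                    "mean_suppression_pct": float(np.mean(sups)),
                    "median_suppression_pct": float(np.median(sups)),
                    "max_suppression_pct": float(np.max(sups)),
                    "mean_suppression_axisfirst_pct": float(
                        np.mean([np.mean(pa) for pa in per_axis])
                    ),
                    "max_peak_windowed_pct": float(np.max(peaks)),
                    "mean_occurrence_pct": float(np.mean(occs)),
                    "mean_torque_suppression_pct": float(np.mean(tsups)),
                }
            )
    return pd.DataFrame(rows)
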