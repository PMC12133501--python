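"""The five-term shaped reward of the tremor-suppression environment.

    r_t = w_a r^a + w_tau r^tau + w_F r^F + w_as r^as + w_u r^u

* ``r^a``   rewards covering every tremor-affected axis,
* ``r^tau`` rewards reducing tremor torque on the affected axes,
* ``r^F``   rewards minimal total actuator force,
* ``r^as``  penalizes rough (large second-difference) force commands,
* ``r^u``   penalizes torque leaked onto non-tremor axes.

Two printed-form ambiguities are resolved behind flags.  The axis term is
weighted twice in the literal reading (r^a = w_a * n_a is again
multiplied by w_a in the total); ``single_weight_axes=True`` applies the
weight once.  The smoothness term as printed is a positive quantity added
with positive weight although it is described as a penalty; the default
negates it so constant forces score 0 and rough forces score below, and
``smoothness_as_printed=True`` restores the literal sign.  The unwanted
torque exponent uses the summed absolute torque so sign cancellation
across axes cannot inflate the reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Published sub-reward weights.
DEFAULT_WEIGHTS = {"wa": 0.5, "wtau": 0.9, "wF": 0.05, "was": 0.05, "wu": 0.5}


@dataclass
class RewardConfig:
    wa: float = DEFAULT_WEIGHTS["wa"]
    wtau: float = DEFAULT_WEIGHTS["wtau"]
    wF: float = DEFAULT_WEIGHTS["wF"]
    was: float = DEFAULT_WEIGHTS["was"]
    wu: float = DEFAULT_WEIGHTS["wu"]
    single_weight_axes: bool = False
    smoothness_as_printed: bool = False


def reward_axes(n_axes: int, wa: float = DEFAULT_WEIGHTS["wa"]) -> float:
    """Axis-coverage sub-reward r^a = w_a * n_a."""
    if n_axes < 0:
        raise ValueError("n_axes must be >= 0")
    return wa * n_axes


def reward_torque(tau_e: np.ndarray, tau_t: np.ndarray) -> float:
    """Torque-suppression sub-reward on the affected axes.

    r^tau = exp(-mean_i (|tau_e_i| - |tau_t_i|) / (|tau_t_i| + 1)); > 1
    iff the exoskeleton reduced tremor torque on average, exactly 1 at no
    change.
    """
    tau_e = np.atleast_1d(np.asarray(tau_e, dtype=float))
    tau_t = np.atleast_1d(np.asarray(tau_t, dtype=float))
    if tau_e.shape != tau_t.shape or tau_e.size == 0:
        raise ValueError("tau_e and tau_t must be equal-length, non-empty")
    ratio = (np.abs(tau_e) - np.abs(tau_t)) / (np.abs(tau_t) + 1.0)
    return float(np.exp(-np.mean(ratio)))


def reward_force(forces: np.ndarray, Fe: float, Fs: float) -> float:
    """Minimal-force sub-reward r^F = exp(-sum_i F_i / (Fe + Fs))."""
    forces = np.asarray(forces, dtype=float)
    return float(np.exp(-np.sum(forces) / (Fe + Fs)))


def reward_smoothness(
    force_history: np.ndarray,
    Fe: float,
    Fs: float,
    as_printed: bool = False,
) -> float:
    """Actuator-smoothness sub-reward from a 3-step force history.

    magnitude = sum_i (F_i(t) - 2 F_i(t-1) + F_i(t-2))^2 / (N (Fe+Fs)^2)
    over the N actuators; returned negated by default so it acts as a
    penalty (0 for constant forces).
    """
    hist = np.asarray(force_history, dtype=float)
    if hist.ndim != 2 or hist.shape[0] != 3:
        raise ValueError("force_history must be 3 steps x N actuators")
    n = hist.shape[1]
    second_diff = hist[2] - 2.0 * hist[1] + hist[0]
    magnitude = float(np.sum(second_diff**2) / (n * (Fe + Fs) ** 2))
    return magnitude if as_printed else -magnitude


def reward_unwanted(tau_u: np.ndarray, Fe: float, Fs: float) -> float:
    """Unwanted-torque sub-reward r^u = exp(-sum_i |tau_u_i| / (Fe+Fs)^2).

    ``tau_u`` holds the exoskeleton-created torques on the axes not
    affected by tremor; 1 when those axes are left untouched.
    """
    tau_u = np.asarray(tau_u, dtype=float)
    return float(np.exp(-np.sum(np.abs(tau_u)) / (Fe + Fs) ** 2))


@dataclass
class RewardBreakdown:
    """One step's sub-rewards and their weighted total."""

    axes: float
    torque: float
    force: float
    smoothness: float
    unwanted: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "axes": self.axes,
            "torque": self.torque,
            "force": self.force,
            "smoothness": self.smoothness,
            "unwanted": self.unwanted,
            "total": self.total,
        }


def total_reward(
    n_axes: int,
    tau_e: np.ndarray,
    tau_t: np.ndarray,
    forces: np.ndarray,
    force_history: np.ndarray,
    tau_u: np.ndarray,
    Fe: float,
    Fs: float,
    config: RewardConfig | None = None,
) -> RewardBreakdown:
    """Weighted five-term reward with logged components."""
    cfg = config or RewardConfig()
    r_a = (
        float(n_axes)
        if cfg.single_weight_axes
        else reward_axes(n_axes, cfg.wa)
    )
    r_tau = reward_torque(tau_e, tau_t)
    r_F = reward_force(forces, Fe, Fs)
    r_as = reward_smoothness(force_history, Fe, Fs, as_printed=cfg.smoothness_as_printed)
    r_u = reward_unwanted(tau_u, Fe, Fs)
    total = (
        cfg.wa * r_a
        + cfg.wtau * r_tau
        + cfg.wF * r_F
        + cfg.was * r_as
        + cfg.wu * r_u
    )
    return RewardBreakdown(r_a, r_tau, r_F, r_as, r_u, total)


def recompute_total(breakdown: RewardBreakdown, config: RewardConfig | None = None) -> float:
    """Re-assemble the weighted sum from logged components (bookkeeping check)."""
    cfg = config or RewardConfig()
    return (
        cfg.wa * breakdown.axes
        + cfg.wtau * breakdown.torque
        + cfg.wF * breakdown.force
        + cfg.was * breakdown.smoothness
        + cfg.wu * breakdown.unwanted
    )
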