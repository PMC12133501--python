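"""Parkinsonian tremor synthesis.

Rest tremor in Parkinson's disease is well approximated by the
superposition of two sine waves — a first harmonic in the 4–6 Hz band and
a second harmonic at roughly twice that frequency — plus a stochastic
component.  This module samples tremor parameters from configurable
uniform ranges (training vs. testing profiles for dynamics
randomization), synthesizes the two-harmonic acceleration waveform with
additive Gaussian noise, normalizes it to unit peak, and converts it to
per-joint torque via a per-axis maximum-torque table.  Tremor is present
at every simulation step, and when several joint axes are affected they
share the same frequencies (and by default phases), which is what couples
the oscillation across axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import N_JOINTS, load_torque_scale

#: Uniform sampling ranges for the tremor and environment randomization.
TREMOR_RANGES = {
    "training": {
        "f1": (4.0, 6.0),  # Hz, first harmonic
        "f2": (8.0, 12.0),  # Hz, second harmonic
        "amplitude": (0.1, 1.0),  # fraction of per-axis max torque
    },
    "testing": {
        "f1": (3.75, 6.25),
        "f2": (7.5, 12.5),
        "amplitude": (0.05, 1.05),
    },
}

DEFAULT_NOISE_SIGMA = 0.1


class TremorError(ValueError):
    """Raised for invalid tremor specifications."""


@dataclass
class TremorSpec:
    """Sampled parameters of one tremor episode.

    ``affected_axes`` are 0-based joint indices (0..6 for q1..q7); one
    (f1, f2) frequency pair is shared by every affected axis.
    """

    affected_axes: tuple[int, ...]
    f1: float
    f2: float
    amplitude_scale: float
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    phase1: float = 0.0
    phase2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.affected_axes = tuple(sorted(set(int(a) for a in self.affected_axes)))
        if not self.affected_axes:
            raise TremorError("affected_axes must be non-empty")
        if any(a < 0 or a >= N_JOINTS for a in self.affected_axes):
            raise TremorError(f"axis indices must be in 0..6, got {self.affected_axes}")
        if self.f1 <= 0 or self.f2 <= 0:
            raise TremorError("harmonic frequencies must be positive")
        if not 0 <= self.amplitude_scale <= 1.05:
            raise TremorError(
                f"amplitude_scale {self.amplitude_scale} outside [0, 1.05]"
            )


@dataclass
class TremorSeries:
    """Per-axis tremor torque time series (N*m), zero off the affected axes."""

    dt: float
    torques: np.ndarray  # (n_steps, 7)
    spec: TremorSpec

    def __post_init__(self) -> None:
        self.torques = np.asarray(self.torques, dtype=float)
        if self.torques.ndim != 2 or self.torques.shape[1] != N_JOINTS:
            raise TremorError(f"torques must be (n, 7), got {self.torques.shape}")


def sample_tremor_spec(
    ranges: str | dict,
    affected_axes: tuple[int, ...],
    rng: np.random.Generator,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> TremorSpec:
    """Draw tremor parameters uniformly and independently from their ranges.

    ``ranges`` is ``"training"``, ``"testing"`` or an explicit mapping with
    ``f1``/``f2``/``amplitude`` bounds.  Phases are uniform on [0, 2pi) and
    shared across the affected axes.
    """
    if not affected_axes:
        raise TremorError("affected_axes must be non-empty")
    if isinstance(ranges, str):
        try:
            ranges = TREMOR_RANGES[ranges]
        except KeyError as exc:
            raise TremorError(
                f"unknown range profile {ranges!r}; use 'training' or 'testing'"
            ) from exc
    return TremorSpec(
        affected_axes=tuple(affected_axes),
        f1=float(rng.uniform(*ranges["f1"])),
        f2=float(rng.uniform(*ranges["f2"])),
        amplitude_scale=float(rng.uniform(*ranges["amplitude"])),
        noise_sigma=noise_sigma,
        phase1=float(rng.uniform(0, 2 * np.pi)),
        phase2=float(rng.uniform(0, 2 * np.pi)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def synthesize_acceleration(
    spec: TremorSpec, n_steps: int, dt: float
) -> np.ndarray:
    """Two-harmonic tremor acceleration waveform, unit peak, shape (n, 7).

    signal = sin(2*pi*f1*t + phi1) + sin(2*pi*f2*t + phi2) + eps with
    eps ~ N(0, noise_sigma^2) i.i.d. per step, then normalized to peak
    magnitude 1.  The identical waveform is placed on every affected axis
    (shared frequencies and phases); unaffected axes stay zero.
    """
    if n_steps < 2:
        raise TremorError("n_steps must be >= 2")
    nyquist = 1.0 / (2.0 * dt)
    if spec.f2 >= nyquist:
        raise TremorError(
            f"dt={dt} puts the second harmonic {spec.f2} Hz at or above the "
            f"Nyquist frequency {nyquist} Hz"
        )
    t = np.arange(n_steps) * dt
    signal = np.sin(2 * np.pi * spec.f1 * t + spec.phase1) + np.sin(
        2 * np.pi * spec.f2 * t + spec.phase2
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=n_steps)
    peak = np.max(np.abs(signal))
    if peak > 0:
        signal = signal / peak
    accel = np.zeros((n_steps, N_JOINTS))
    for axis in spec.affected_axes:
        accel[:, axis] = signal
    return accel


def acceleration_to_torque(
    accel: np.ndarray,
    spec: TremorSpec,
    dt: float,
    torque_scale_table: np.ndarray | None = None,
) -> TremorSeries:
    """Scale the normalized acceleration into joint torques (N*m).

    Per axis: torque = accel * amplitude_scale * max_torque[axis], so a
    tremor at amplitude_scale=1 peaks at the configured per-axis maximum
    tremor torque.
    """
    if torque_scale_table is None:
        torque_scale_table = load_torque_scale()
    torque_scale_table = np.asarray(torque_scale_table, dtype=float)
    if torque_scale_table.shape != (N_JOINTS,):
        raise TremorError(
            f"torque scale table must have 7 entries, got {torque_scale_table.shape}"
        )
    accel = np.asarray(accel, dtype=float)
    torques = np.zeros_like(accel)
    for axis in spec.affected_axes:
        torques[:, axis] = accel[:, axis] * spec.amplitude_scale * torque_scale_table[axis]
    return TremorSeries(dt=dt, torques=torques, spec=spec)


def generate_tremor_series(
    spec: TremorSpec,
    n_steps: int,
    dt: float,
    torque_scale_table: np.ndarray | None = None,
) -> TremorSeries:
    """Convenience: synthesize acceleration and convert to torque."""
    accel = synthesize_acceleration(spec, n_steps, dt)
    return acceleration_to_torque(accel, spec, dt, torque_scale_table)
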