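"""Temporally correlated (pink, 1/f) exploration noise.

White action noise is a poor fit for fine force control: consecutive
uncorrelated kicks make the commanded forces rough and the induced
torques erratic.  Pink noise — power spectral density falling off as 1/f,
halfway between white (flat) and brown (1/f^2) — keeps exploration
temporally coherent, which both smooths the applied forces and explores
the action space at the time scales the arm dynamics actually respond to.

The generator synthesizes a full episode of noise spectrally (random
phases, amplitudes proportional to f^(-1/2), inverse FFT), normalizes
each action dimension to unit variance, and serves it sample by sample;
``reset`` regenerates for the next episode.
"""

from __future__ import annotations

import numpy as np


def pink_noise(
    n_steps: int, n_dims: int, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """(n_steps, n_dims) noise with PSD ~ 1/f**exponent, unit variance per dim."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    freqs = np.fft.rfftfreq(n_steps)
    amplitude = np.zeros_like(freqs)
    amplitude[1:] = freqs[1:] ** (-exponent / 2.0)
    # random complex spectrum with the prescribed amplitude envelope
    spectrum = amplitude[:, None] * (
        rng.standard_normal((len(freqs), n_dims))
        + 1j * rng.standard_normal((len(freqs), n_dims))
    )
    spectrum[0] = 0.0
    samples = np.fft.irfft(spectrum, n=n_steps, axis=0)
    std = samples.std(axis=0)
    std[std == 0] = 1.0
    return samples / std


class PinkNoiseProcess:
    """Stateful per-episode pink-noise stream for action exploration."""

    def __init__(
        self,
        n_dims: int,
        episode_steps: int,
        rng: np.random.Generator,
        exponent: float = 1.0,
    ) -> None:
        self.n_dims = n_dims
        self.episode_steps = max(int(episode_steps), 2)
        self.exponent = exponent
        self._rng = rng
        self.reset()

    def reset(self) -> None:
        """Regenerate the noise buffer (call at episode start)."""
        self._buffer = pink_noise(
            self.episode_steps, self.n_dims, self._rng, self.exponent
        )
        self._i = 0

    def sample(self) -> np.ndarray:
        """Next noise vector; transparently regenerates when exhausted."""
        if self._i >= len(self._buffer):
            self.reset()
        out = self._buffer[self._i]
        self._i += 1
        return out


def explore_action(
    policy_action: np.ndarray, noise: np.ndarray, scale: float
) -> np.ndarray:
    """Exploratory action: policy action plus scaled noise, clipped to [-1, 1]."""
    return np.clip(np.asarray(policy_action, dtype=float) + scale * noise, -1.0, 1.0)
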