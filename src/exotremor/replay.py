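"""Loss-adjusted prioritized (LAP) replay, split into per-movement sub-buffers.

LAP samples transition i with probability

    p_i = max(|delta_i|^alpha, 1) / sum_j max(|delta_j|^alpha, 1),

where delta_i is the last TD error of the transition; the floor at 1
leaves small-error transitions uniformly sampled (and pairs with a Huber
critic loss), while large-error transitions are oversampled at a rate
governed by alpha.

Because reference movements have different trajectory lengths, a single
buffer would over-represent the longer movements.  The replay is
therefore divided into one LAP buffer per reference movement, and each
batch draws equally many transitions from every sub-buffer.
"""

from __future__ import annotations

import numpy as np


def lap_priority(delta: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """LAP priority max(|delta|^alpha, 1)."""
    return np.maximum(np.abs(delta) ** alpha, 1.0)


class LAPBuffer:
    """Ring buffer with priority-proportional sampling."""

    def __init__(
        self, capacity: int, obs_dim: int, act_dim: int, alpha: float = 0.4
    ) -> None:
        self.capacity = int(capacity)
        self.alpha = alpha
        self.obs = np.zeros((capacity, obs_dim))
        self.act = np.zeros((capacity, act_dim))
        self.rew = np.zeros(capacity)
        self.next_obs = np.zeros((capacity, obs_dim))
        self.done = np.zeros(capacity)
        self.priority = np.zeros(capacity)
        self.size = 0
        self._head = 0

    def add(self, s, a, r, s2, done) -> None:
        i = self._head
        self.obs[i] = s
        self.act[i] = a
        self.rew[i] = r
        self.next_obs[i] = s2
        self.done[i] = float(done)
        # new transitions enter at the current maximum priority (>= 1)
        self.priority[i] = self.priority[: self.size].max() if self.size else 1.0
        self._head = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def probabilities(self) -> np.ndarray:
        p = self.priority[: self.size]
        return p / p.sum()

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Indices of k transitions drawn with LAP probabilities."""
        if self.size == 0:
            raise ValueError("cannot sample from an empty buffer")
        return rng.choice(self.size, size=k, replace=True, p=self.probabilities())

    def update_priorities(self, indices: np.ndarray, td_errors: np.ndarray) -> None:
        self.priority[indices] = lap_priority(td_errors, self.alpha)


class SubBufferedReplay:
    """One LAP buffer per reference movement; batches split equally."""

    def __init__(
        self,
        movement_ids: list[str],
        capacity_per_movement: int,
        obs_dim: int,
        act_dim: int,
        alpha: float = 0.4,
    ) -> None:
        if not movement_ids:
            raise ValueError("need at least one movement id")
        self.buffers = {
            m: LAPBuffer(capacity_per_movement, obs_dim, act_dim, alpha)
            for m in movement_ids
        }

    def add(self, movement_id: str, s, a, r, s2, done) -> None:
        self.buffers[movement_id].add(s, a, r, s2, done)

    @property
    def size(self) -> int:
        return sum(b.size for b in self.buffers.values())

    def min_size(self) -> int:
        return min(b.size for b in self.buffers.values())

    def sample_batch(
        self, batch_size: int, rng: np.random.Generator
    ) -> dict[str, dict[str, np.ndarray]]:
        """Equal per-movement allocation of ``batch_size`` transitions.

        Returns {movement_id: {"idx", "obs", "act", "rew", "next_obs",
        "done"}}; ``batch_size`` must divide evenly by the number of
        sub-buffers.
        """
        n = len(self.buffers)
        if batch_size % n:
            raise ValueError(
                f"batch_size {batch_size} not divisible by {n} sub-buffers"
            )
        k = batch_size // n
        out = {}
        for m, buf in sorted(self.buffers.items()):
            idx = buf.sample(k, rng)
            out[m] = {
                "idx": idx,
                "obs": buf.obs[idx],
                "act": buf.act[idx],
                "rew": buf.rew[idx],
                "next_obs": buf.next_obs[idx],
                "done": buf.done[idx],
            }
        return out

    def update_priorities(
        self, movement_id: str, indices: np.ndarray, td_errors: np.ndarray
    ) -> None:
        self.buffers[movement_id].update_priorities(indices, td_errors)
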