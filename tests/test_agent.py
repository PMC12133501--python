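"""Learner components: networks, noise, replay, targets, and a short
end-to-end training run on a toy task."""

import numpy as np
import pytest
from scipy import stats

from exotremor.nn import MLP, Adam
from exotremor.noise import PinkNoiseProcess, explore_action, pink_noise
from exotremor.replay import LAPBuffer, SubBufferedReplay, lap_priority
from exotremor.td7 import AgentConfig, TD7Agent, TD7Networks, critic_target


# -- neural nets -------------------------------------------------------------


def test_mlp_backward_matches_numerical_gradients(rng):
    net = MLP([4, 6, 2], rng, output_activation="tanh")
    x = rng.normal(size=(3, 4))
    tgt = rng.normal(size=(3, 2))
    out = net.forward(x, cache=True)
    dx = net.backward(2 * (out - tgt))
    eps = 1e-6
    for i in range(3):
        for j in range(4):
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            num = (np.sum((net(xp) - tgt) ** 2) - np.sum((net(xm) - tgt) ** 2)) / (2 * eps)
            assert dx[i, j] == pytest.approx(num, abs=1e-6)


def test_adam_reduces_regression_loss(rng):
    net = MLP([3, 16, 1], rng)
    opt = Adam(net, lr=1e-2)
    x = rng.normal(size=(64, 3))
    y = 2.0 * x[:, :1] - x[:, 1:2] + 0.5 * x[:, 2:]
    losses = []
    for _ in range(200):
        pred = net.forward(x, cache=True)
        losses.append(float(np.mean((pred - y) ** 2)))
        net.backward(2 * (pred - y) / len(x))
        opt.step()
    assert losses[-1] < 0.05 * losses[0]


# -- exploration noise -------------------------------------------------------


def test_pink_noise_psd_slope():
    """Log-log PSD slope sits between white (0) and brown (-2)."""
    x = pink_noise(2**16, 1, np.random.default_rng(0))[:, 0]
    freqs = np.fft.rfftfreq(len(x))
    psd = np.abs(np.fft.rfft(x)) ** 2
    sel = slice(1, len(freqs) // 2)
    slope, _ = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)
    assert -1.5 < slope < -0.5


def test_pink_noise_more_correlated_than_white():
    """Lag-1 autocorrelation separates pink from equal-variance white noise."""
    rng = np.random.default_rng(1)
    pink = pink_noise(4096, 1, rng)[:, 0]
    white = rng.standard_normal(4096)

    def ac1(v):
        return float(np.corrcoef(v[:-1], v[1:])[0, 1])

    assert ac1(pink) > ac1(white) + 0.3


def test_pink_noise_process_stream_and_determinism():
    p1 = PinkNoiseProcess(7, 50, np.random.default_rng(3))
    p2 = PinkNoiseProcess(7, 50, np.random.default_rng(3))
    s1 = np.stack([p1.sample() for _ in range(60)])  # crosses a regeneration
    s2 = np.stack([p2.sample() for _ in range(60)])
    assert np.array_equal(s1, s2)
    assert s1.shape == (60, 7)


def test_explore_action_scale_zero_and_clipping():
    a = np.array([0.5, -0.5, 0.0, 1.0, -1.0, 0.2, -0.2])
    noise = np.full(7, 10.0)
    assert np.array_equal(explore_action(a, noise, 0.0), a)
    out = explore_action(a, noise, 1.0)
    assert np.all(out <= 1.0) and np.all(out >= -1.0)


# -- replay ------------------------------------------------------------------


def test_lap_priority_formula():
    assert lap_priority(0.5, 1.0) == 1.0  # clamp region
    assert lap_priority(2.0, 1.0) == 2.0
    assert lap_priority(4.0, 0.5) == 2.0
    deltas = np.linspace(0, 5, 50)
    pr = lap_priority(deltas, 0.7)
    assert np.all(np.diff(pr) >= 0)


def test_equal_split_across_sub_buffers(rng):
    replay = SubBufferedReplay(["a", "b", "c", "d"], 1000, 4, 2)
    for m in "abcd":
        for i in range(50):
            replay.add(m, np.zeros(4), np.zeros(2), 0.0, np.zeros(4), False)
    batch = replay.sample_batch(256, rng)
    assert sorted(batch) == ["a", "b", "c", "d"]
    for b in batch.values():
        assert len(b["idx"]) == 64


def test_uniform_sampling_when_priorities_equal(rng):
    buf = LAPBuffer(20, 1, 1, alpha=0.4)
    for _ in range(20):
        buf.add([0.0], [0.0], 0.0, [0.0], False)
    counts = np.bincount(buf.sample(100_000, rng), minlength=20)
    chi2 = stats.chisquare(counts)
    assert chi2.pvalue > 0.01


def test_prioritized_sampling_matches_lap_probabilities(rng):
    """A 10x-priority transition is drawn ~10x as often."""
    buf = LAPBuffer(10, 1, 1, alpha=1.0)
    for _ in range(10):
        buf.add([0.0], [0.0], 0.0, [0.0], False)
    buf.update_priorities(np.arange(10), np.ones(10))
    buf.update_priorities(np.array([0]), np.array([10.0]))
    counts = np.bincount(buf.sample(100_000, rng), minlength=10)
    ratio = counts[0] / counts[1:].mean()
    assert ratio == pytest.approx(10.0, rel=0.1)


def test_replay_never_mixes_movements(rng):
    replay = SubBufferedReplay(["m1", "m2"], 100, 1, 1)
    for i in range(30):
        replay.add("m1", [1.0], [0.0], 1.0, [1.0], False)
        replay.add("m2", [2.0], [0.0], 2.0, [2.0], False)
    batch = replay.sample_batch(40, rng)
    assert np.all(batch["m1"]["obs"] == 1.0)
    assert np.all(batch["m2"]["obs"] == 2.0)


def test_ring_buffer_overwrites_oldest():
    buf = LAPBuffer(5, 1, 1)
    for i in range(8):
        buf.add([float(i)], [0.0], 0.0, [0.0], False)
    assert buf.size == 5
    assert set(buf.obs[:, 0]) == {3.0, 4.0, 5.0, 6.0, 7.0}


# -- TD7 targets -------------------------------------------------------------


@pytest.fixture
def nets():
    return TD7Networks(4, 2, AgentConfig(embed_dim=4, encoder_hidden=(8,),
                                         actor_hidden=(8,), critic_hidden=(8,)),
                       np.random.default_rng(0))


def test_terminal_and_myopic_targets(nets):
    s2 = np.ones((1, 4))
    y_term = critic_target(nets, np.array([2.5]), s2, np.array([1.0]), 0.99)
    assert y_term[0] == pytest.approx(2.5)
    y_myopic = critic_target(nets, np.array([2.5]), s2, np.array([0.0]), 0.0)
    assert y_myopic[0] == pytest.approx(2.5)


def test_clipped_double_q_uses_minimum(nets):
    """The bootstrap never exceeds either single critic's estimate."""
    s2 = np.random.default_rng(1).normal(size=(8, 4))
    zs = nets.f_t(s2)
    a = np.clip(
        nets.action_scale * nets.actor_t(np.concatenate([zs, s2], axis=1)),
        -1.0, 1.0,
    )
    zsa = nets.g_t(np.concatenate([zs, a], axis=1))
    q_in = np.concatenate([zsa, zs, s2, a], axis=1)
    q1, q2 = nets.q1_t(q_in)[:, 0], nets.q2_t(q_in)[:, 0]
    y = critic_target(nets, np.zeros(8), s2, np.zeros(8), 1.0)
    assert np.allclose(y, np.minimum(q1, q2))
    assert np.all(y <= q1 + 1e-12) and np.all(y <= q2 + 1e-12)


def test_actor_starts_near_zero_force():
    cfg = AgentConfig(embed_dim=4, encoder_hidden=(8,), actor_hidden=(8,),
                      critic_hidden=(8,), init_action_bias=-1.0)
    nets = TD7Networks(4, 2, cfg, np.random.default_rng(0))
    a = nets.act(np.zeros(4))
    assert np.all(a < -0.3)  # biased toward the all-off corner


# -- end-to-end learning sanity ----------------------------------------------


class _ToyEnv:
    """Reactive 1-step-credit task: reward peaks when a tracks W s."""

    observation_dim = 4
    action_dim = 2
    episode_length = 8

    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)
        self.W = 0.5 * np.array([[1.0, 0, -1, 0], [0, 1.0, 0, -1]])

    def reset(self, seed=None):
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        self.t = 0
        self.s = self.rng.uniform(-1, 1, 4)
        return self.s, {}

    def step(self, a):
        r = float(2.0 - np.sum((a - self.W @ self.s) ** 2))
        self.t += 1
        self.s = self.rng.uniform(-1, 1, 4)
        return self.s, r, self.t >= self.episode_length, False, {}


def test_td7_learns_toy_task():
    cfg = AgentConfig(seed=0, start_steps=200, eval_freq=0, batch_size=32,
                      gamma=0.5, embed_dim=8, encoder_hidden=(32,),
                      actor_hidden=(32, 32), critic_hidden=(32, 32),
                      init_action_bias=0.0)
    agent = TD7Agent(4, 2, ["m"], cfg)
    log = agent.train({"m": _ToyEnv(0)}, total_steps=3000)
    rew = np.array(log.episode_rewards)
    assert rew[-10:].mean() > rew[:10].mean() + 4.0
    assert rew[-10:].mean() > 13.0  # near the 16 optimum


def test_zero_training_steps_returns_initialized_agent():
    agent = TD7Agent(4, 2, ["m"], AgentConfig(seed=1, embed_dim=4,
                                              encoder_hidden=(8,),
                                              actor_hidden=(8,),
                                              critic_hidden=(8,)))
    log = agent.train({"m": _ToyEnv(0)}, total_steps=0)
    assert log.steps == [] and log.episode_rewards == []
    assert agent.nets.act(np.zeros(4)).shape == (2,)


def test_checkpoint_scores_non_decreasing():
    cfg = AgentConfig(seed=0, start_steps=100, eval_freq=300, eval_episodes=1,
                      batch_size=32, gamma=0.5, embed_dim=8,
                      encoder_hidden=(16,), actor_hidden=(16,),
                      critic_hidden=(16,), init_action_bias=0.0)
    agent = TD7Agent(4, 2, ["m"], cfg)
    log = agent.train({"m": _ToyEnv(0)}, total_steps=1500)
    scores = log.checkpoint_scores
    assert len(scores) >= 3
    assert all(b >= a for a, b in zip(scores, scores[1:]))


def test_checkpoint_save_load_roundtrip(tmp_path):
    agent = TD7Agent(4, 2, ["m"], AgentConfig(seed=2, embed_dim=4,
                                              encoder_hidden=(8,),
                                              actor_hidden=(8,),
                                              critic_hidden=(8,)))
    path = agent.save_checkpoint(tmp_path / "ckpt.npz")
    snap, meta = TD7Agent.load_checkpoint(path)
    assert meta["obs_dim"] == 4 and meta["act_dim"] == 2
    obs = np.ones(4) * 0.3
    a_direct = agent.nets.act(obs, use_checkpoint=True)
    a_loaded = agent.nets.act(obs, params=snap)
    assert np.allclose(a_direct, a_loaded)
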