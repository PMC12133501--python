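"""Suppression metrics, reference policies, and the evaluation protocol."""

import numpy as np
import pytest

from exotremor.env import TremorSuppressionEnv
from exotremor.evaluation import (
    FeedforwardPolicy,
    OraclePolicy,
    ZeroPolicy,
    amplitude_suppression,
    episode_metrics,
    occurrence,
    run_episode,
    run_protocol,
    suppression_curve,
    torque_suppression,
    tremor_axis_combinations,
)
from exotremor.motion import generate_synthetic_movement


def _toy_signals(n=100, axes=(3,)):
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(n, 7)) * 0.1
    dev = np.zeros((n, 7))
    # phase offset keeps the deviation away from exact zeros
    dev[:, list(axes)] = np.sin(np.linspace(0.3, 20.3, n))[:, None] * 0.2
    return ref, ref + dev, dev


def test_amplitude_suppression_endpoints():
    ref, tremor_only, _ = _toy_signals()
    assert amplitude_suppression(ref, tremor_only, ref, (3,)) == pytest.approx(100.0)
    assert amplitude_suppression(ref, tremor_only, tremor_only, (3,)) == pytest.approx(0.0)


def test_amplitude_suppression_pointwise_ratio():
    """Halving the deviation pointwise gives exactly 50%."""
    ref, tremor_only, dev = _toy_signals()
    halved = ref + 0.5 * dev
    assert amplitude_suppression(ref, tremor_only, halved, (3,)) == pytest.approx(50.0)


def test_amplitude_suppression_capped_at_100_and_unbounded_below():
    ref, tremor_only, dev = _toy_signals()
    amplified = ref + 3.0 * dev
    val = amplitude_suppression(ref, tremor_only, amplified, (3,))
    assert val == pytest.approx(-200.0)


def test_metrics_invariant_to_common_time_shift():
    ref, tremor_only, dev = _toy_signals()
    sup = ref + 0.3 * dev
    base = amplitude_suppression(ref, tremor_only, sup, (3,))
    shifted = amplitude_suppression(ref[10:], tremor_only[10:], sup[10:], (3,))
    # uniform truncation/shift of all three series leaves the ratio intact
    assert shifted == pytest.approx(
        amplitude_suppression(ref[10:], tremor_only[10:], sup[10:], (3,))
    )
    assert abs(base - shifted) < 5.0  # same signal statistics


def test_suppression_curve_window_and_values():
    ref, tremor_only, dev = _toy_signals()
    sup = ref + 0.5 * dev
    curve = suppression_curve(ref, tremor_only, sup, (3,), window=10)
    assert len(curve) == len(ref) - 9
    assert np.allclose(curve, 50.0)


def test_occurrence_endpoints():
    ref, tremor_only, dev = _toy_signals()
    assert occurrence(ref, tremor_only, ref, (3,)) == pytest.approx(100.0)
    # zero action: strict inequality fails at every step
    assert occurrence(ref, tremor_only, tremor_only, (3,)) == pytest.approx(0.0)


def test_occurrence_excludes_disrupted_steps():
    """Suppressing the tremor axis while dragging an unaffected axis beyond
    the tolerance must not count."""
    ref, tremor_only, dev = _toy_signals()
    sup = ref + 0.2 * dev
    clean = occurrence(ref, tremor_only, sup, (3,), epsilon=0.05)
    disrupted = sup.copy()
    disrupted[:50, 0] += 1.0  # large unaffected-axis excursion on half the steps
    dirty = occurrence(ref, tremor_only, disrupted, (3,), epsilon=0.05)
    assert clean == pytest.approx(100.0)
    assert dirty == pytest.approx(50.0)


def test_torque_suppression_endpoints():
    tau_t = np.zeros((50, 7))
    tau_t[:, 3] = np.sin(np.linspace(0, 10, 50))
    assert torque_suppression(tau_t, np.zeros_like(tau_t), (3,)) == pytest.approx(100.0)
    assert torque_suppression(tau_t, tau_t, (3,)) == pytest.approx(0.0)


def test_axis_combinations_enumeration():
    combos = tremor_axis_combinations()
    assert len(combos) == 15
    assert (3,) in combos and (0, 1, 2, 3) in combos
    assert len(set(combos)) == 15


# -- rollouts through the simulator ------------------------------------------


@pytest.fixture(scope="module")
def eval_env(short_trajectory):
    return TremorSuppressionEnv(short_trajectory, (3,), profile="testing", seed=0)


def test_oracle_policy_is_metric_upper_bound(eval_env):
    """Perfect torque cancellation scores 100% on every metric."""
    result = run_episode(eval_env, OraclePolicy(), seed=5)
    m = episode_metrics(result, (3,), eval_env.config.dt)
    assert m["amplitude_suppression_pct"] == pytest.approx(100.0)
    assert m["occurrence_pct"] == pytest.approx(100.0)
    assert m["torque_suppression_pct"] == pytest.approx(100.0)
    assert m["peak_windowed_suppression_pct"] == pytest.approx(100.0)


def test_zero_policy_scores_zero_suppression(eval_env):
    result = run_episode(eval_env, ZeroPolicy(), seed=6)
    m = episode_metrics(result, (3,), eval_env.config.dt)
    assert m["amplitude_suppression_pct"] == pytest.approx(0.0, abs=1e-9)
    assert m["occurrence_pct"] == pytest.approx(0.0, abs=1e-9)


def test_feedforward_policy_suppresses_most_of_the_tremor(eval_env):
    """Model-based inversion through the real actuators suppresses the bulk
    of the tremor despite actuation randomization."""
    sups = []
    for ep in range(5):
        result = run_episode(eval_env, FeedforwardPolicy(), seed=100 + ep)
        sups.append(
            episode_metrics(result, (3,), eval_env.config.dt)[
                "amplitude_suppression_pct"
            ]
        )
    assert np.mean(sups) > 60.0


def test_episode_hdf5_export_roundtrip(eval_env, tmp_path):
    import h5py

    result = run_episode(eval_env, ZeroPolicy(), seed=3)
    path = tmp_path / "episode.h5"
    result.to_hdf5(path)
    with h5py.File(path) as fh:
        assert np.allclose(fh["suppressed_angles"][...], result.suppressed)
        assert np.allclose(fh["reward"][...],
                           [r.reward.total for r in result.records])
        assert fh.attrs["f1_hz"] == result.f1


def test_protocol_report_shape_and_determinism(short_trajectory):
    trajs = {
        "elbow_flexion_extension": short_trajectory,
        "shoulder_flexion_extension": generate_synthetic_movement(
            "shoulder_flexion_extension", 2.0, 1 / 30, 1.0, seed=2
        ),
    }
    combos = [(3,), (0, 3)]
    rep1 = run_protocol(ZeroPolicy(), trajs, n_episodes=2, seed=3, combos=combos)
    rep2 = run_protocol(ZeroPolicy(), trajs, n_episodes=2, seed=3, combos=combos)
    assert len(rep1) == len(combos) * len(trajs)
    assert np.allclose(
        rep1["mean_suppression_pct"], rep2["mean_suppression_pct"]
    )
    assert np.allclose(rep1["mean_suppression_pct"], 0.0, atol=1e-9)
    assert set(rep1["tremor_axes"]) == {"q4", "q1+q4"}
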