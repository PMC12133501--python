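"""Coupled displacement dynamics and forward kinematics."""

import numpy as np
import pytest

from exotremor.dynamics import (
    DEFAULT_SUBSTEPS,
    AnatomicalMatrices,
    ArmGeometry,
    DisplacementState,
    DynamicsError,
    forward_kinematics,
    joint_axis_directions,
    load_matrices,
    solve_displacement_step,
    step_from_reference,
)

DT = 1 / 30


def test_matrix_file_loads_with_physical_properties(matrices):
    for m in (matrices.I, matrices.D, matrices.K):
        assert m.shape == (7, 7)
        assert np.allclose(m, m.T)
    assert np.min(np.linalg.eigvalsh(matrices.I)) > 0
    assert np.min(np.linalg.eigvalsh(matrices.D)) >= 0
    assert np.min(np.linalg.eigvalsh(matrices.K)) >= 0


def test_invalid_matrices_rejected():
    eye = np.eye(7)
    with pytest.raises(DynamicsError, match="7x7"):
        AnatomicalMatrices(np.eye(6), eye, eye)
    asym = eye.copy()
    asym[0, 1] = 0.5
    with pytest.raises(DynamicsError, match="symmetric"):
        AnatomicalMatrices(asym, eye, eye)
    with pytest.raises(DynamicsError, match="positive definite"):
        AnatomicalMatrices(-eye, eye, eye)


def test_equilibrium_is_fixed_point(matrices):
    state = solve_displacement_step(matrices, np.zeros(7), DT)
    assert np.all(state.q == 0) and np.all(state.q_dot == 0)


def test_constant_torque_reaches_static_solution(matrices):
    """Long rollout under constant torque converges to q = K^-1 tau."""
    tau = np.array([0.5, -0.3, 0.1, 0.4, 0.0, 0.05, -0.02])
    state = DisplacementState.rest()
    for _ in range(3000):
        state = solve_displacement_step(matrices, tau, DT, init=state)
    expected = np.linalg.solve(matrices.K, tau)
    assert np.allclose(state.q, expected, atol=1e-6)
    assert np.allclose(state.q_dot, 0, atol=1e-6)


def test_linearity_doubling_torque_doubles_displacement(matrices):
    tau = np.array([0.2, 0.1, -0.05, 0.3, 0.01, 0.0, 0.02])
    s1 = solve_displacement_step(matrices, tau, DT)
    s2 = solve_displacement_step(matrices, 2 * tau, DT)
    assert np.allclose(s2.q, 2 * s1.q, atol=1e-12)
    assert np.allclose(s2.q_dot, 2 * s1.q_dot, atol=1e-12)


def test_superposition(matrices, rng):
    """Response to tau_T + tau_O equals sum of separate responses (1e-8)."""
    tau_a = rng.normal(size=7) * 0.5
    tau_b = rng.normal(size=7) * 0.5
    qa = solve_displacement_step(matrices, tau_a, DT).q
    qb = solve_displacement_step(matrices, tau_b, DT).q
    qab = solve_displacement_step(matrices, tau_a + tau_b, DT).q
    assert np.allclose(qab, qa + qb, atol=1e-8)


def test_energy_decay_with_zero_torque(matrices):
    state = DisplacementState(
        np.full(7, 0.1), np.zeros(7), np.zeros(7)
    )
    norms = []
    for _ in range(200):
        state = solve_displacement_step(matrices, np.zeros(7), DT, init=state)
        energy = state.q @ matrices.K @ state.q + state.q_dot @ matrices.I @ state.q_dot
        norms.append(energy)
    assert norms[-1] < norms[0] * 1e-3
    assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))


def test_substep_convergence(matrices):
    tau = np.array([0.3, 0.0, 0.1, 0.5, 0.0, 0.02, 0.0])
    coarse = solve_displacement_step(matrices, tau, DT, n_substeps=DEFAULT_SUBSTEPS)
    fine = solve_displacement_step(matrices, tau, DT, n_substeps=2 * DEFAULT_SUBSTEPS)
    assert np.max(np.abs(coarse.q - fine.q)) < 1e-4


def test_solver_input_validation(matrices):
    with pytest.raises(DynamicsError, match="non-finite"):
        solve_displacement_step(matrices, np.full(7, np.nan), DT)
    with pytest.raises(DynamicsError, match="shape"):
        solve_displacement_step(matrices, np.zeros(6), DT)


def test_step_from_reference_zero_torque_returns_reference(matrices, elbow_trajectory):
    ref = elbow_trajectory.angles[10]
    angles, _, clamped = step_from_reference(
        ref, np.zeros(7), np.zeros(7), matrices, DT
    )
    assert np.array_equal(angles, ref)
    assert not clamped


def test_step_from_reference_perfect_cancellation(matrices, elbow_trajectory):
    ref = elbow_trajectory.angles[10]
    tau_t = np.array([0.0, 0.0, 0.0, 0.7, 0.0, 0.0, 0.0])
    angles, _, _ = step_from_reference(ref, tau_t, -tau_t, matrices, DT)
    assert np.allclose(angles, ref, atol=1e-15)


def test_tremor_propagation_through_coupling(matrices, diagonal_matrices):
    """Elbow-only torque stays on q4 with diagonal matrices but leaks onto
    the coupled axes with off-diagonal I/D/K."""
    tau = np.zeros(7)
    tau[3] = 0.8
    q_diag = solve_displacement_step(diagonal_matrices, tau, DT).q
    q_coupled = solve_displacement_step(matrices, tau, DT).q
    off = [0, 1, 2, 4, 5, 6]
    assert np.allclose(q_diag[off], 0, atol=1e-15)
    assert q_diag[3] != 0
    assert np.any(np.abs(q_coupled[off]) > 1e-9)


def test_clamping_flag(matrices, joint_ranges):
    ref = joint_ranges[:, 1] - 1e-4  # poses at the upper limits
    tau = np.full(7, 5.0)
    angles, _, clamped = step_from_reference(
        ref, tau, np.zeros(7), matrices, DT, joint_ranges=joint_ranges
    )
    assert clamped
    assert np.all(angles <= joint_ranges[:, 1])


# -- forward kinematics ------------------------------------------------------


def test_neutral_pose_geometry(geometry):
    frames = forward_kinematics(np.zeros(7), geometry)
    assert np.allclose(frames.shoulder, 0)
    assert np.allclose(frames.elbow, [0, 0, -geometry.upper_arm_length])
    assert np.allclose(frames.wrist, [0, 0, -geometry.upper_arm_length - geometry.forearm_length])


def test_segment_lengths_conserved(geometry, rng):
    for _ in range(25):
        angles = rng.uniform(-1.2, 1.2, size=7)
        f = forward_kinematics(angles, geometry)
        assert np.linalg.norm(f.elbow - f.shoulder) == pytest.approx(
            geometry.upper_arm_length, abs=1e-9
        )
        assert np.linalg.norm(f.wrist - f.elbow) == pytest.approx(
            geometry.forearm_length, abs=1e-9
        )
        assert np.linalg.norm(f.hand - f.wrist) == pytest.approx(
            geometry.hand_length, abs=1e-9
        )


def test_elbow_flexion_rotates_wrist_about_flexion_axis(geometry):
    """q4 = pi/2 moves the wrist by a quarter turn about the elbow axis."""
    straight = forward_kinematics(np.zeros(7), geometry)
    bent = forward_kinematics(np.array([0, 0, 0, np.pi / 2, 0, 0, 0]), geometry)
    r0 = straight.wrist - straight.elbow
    r1 = bent.wrist - bent.elbow
    assert np.dot(r0, r1) == pytest.approx(0.0, abs=1e-9)  # 90 degrees
    axis = joint_axis_directions(np.zeros(7))[3]
    assert np.dot(r1 - r0, axis) == pytest.approx(0.0, abs=1e-9)  # in-plane
    # positive flexion swings the forearm forward (+x)
    assert r1[0] > 0


def test_joint_axes_are_unit_vectors(rng):
    for _ in range(10):
        axes = joint_axis_directions(rng.uniform(-1, 1, size=7))
        assert np.allclose(np.linalg.norm(axes, axis=1), 1.0)


def test_geometry_validation():
    with pytest.raises(DynamicsError):
        ArmGeometry(upper_arm_length=-0.1)
    with pytest.raises(DynamicsError):
        ArmGeometry(mass_ratio_upper=1.5)
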