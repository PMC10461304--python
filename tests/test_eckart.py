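import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rotoshear.core import Frame, Structure, Trajectory
from rotoshear.eckart import (
    angular_momentum,
    apparent_angular_velocity,
    center_of_mass,
    coriolis_coupling_vector,
    eckart_angular_velocity,
    eckart_rotation,
    finite_difference_velocities,
    inertia_tensor,
    lab_rotation_state,
)
from rotoshear.trajgen import compose, make_rigid_rotor, make_shear_cloud, make_twist

from conftest import DT, OMEGA, OMEGA3


def random_rotation(rng, max_angle=None):
    vec = rng.normal(size=3)
    vec /= np.linalg.norm(vec)
    angle = rng.uniform(0, max_angle) if max_angle else rng.uniform(0, np.pi)
    return Rotation.from_rotvec(angle * vec).as_matrix()


class TestCenterOfMass:
    def test_symmetric_pair(self):
        s = Structure(positions=[[1, 0, 0], [-1, 0, 0]], masses=[1, 1])
        f = Frame(time=0, positions=s.positions)
        com, _ = center_of_mass(f, s)
        np.testing.assert_allclose(com, 0.0, atol=1e-15)

    def test_unequal_masses(self):
        # hand arithmetic: (1*0 + 3*1) / 4 = 0.75
        s = Structure(positions=[[0, 0, 0], [1, 0, 0]], masses=[1, 3])
        f = Frame(time=0, positions=s.positions)
        com, _ = center_of_mass(f, s)
        assert com[0] == pytest.approx(0.75, abs=1e-15)

    def test_shared_velocity(self, toy_structure):
        u = np.array([0.3, -0.1, 0.2])
        f = Frame(
            time=0,
            positions=toy_structure.positions,
            velocities=np.tile(u, (toy_structure.n_beads, 1)),
        )
        _, vcm = center_of_mass(f, toy_structure)
        np.testing.assert_allclose(vcm, u, atol=1e-14)


class TestInertiaTensor:
    def test_single_bead_zero(self):
        s = Structure(positions=[[0.4, 0.2, 0.1]], masses=[3.0])
        f = Frame(time=0, positions=s.positions)
        np.testing.assert_allclose(inertia_tensor(f, s), 0.0, atol=1e-15)

    def test_unit_pair_on_x(self):
        # two unit masses at +-(1,0,0): J = diag(0, 2, 2)
        s = Structure(positions=[[1, 0, 0], [-1, 0, 0]], masses=[1, 1])
        f = Frame(time=0, positions=s.positions)
        np.testing.assert_allclose(
            inertia_tensor(f, s), np.diag([0.0, 2.0, 2.0]), atol=1e-15
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_psd_property(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        s = Structure(
            positions=rng.normal(size=(n, 3)), masses=rng.uniform(0.5, 3.0, n)
        )
        f = Frame(time=0, positions=s.positions)
        J = inertia_tensor(f, s)
        np.testing.assert_allclose(J, J.T, atol=1e-12)
        assert np.linalg.eigvalsh(J).min() > -1e-12


class TestAngularMomentum:
    def test_breathing_frame_zero(self, breathing_traj, toy_structure):
        np.testing.assert_allclose(
            angular_momentum(breathing_traj[5], toy_structure), 0.0, atol=1e-12
        )

    def test_rigid_rotor_L_equals_J_omega(self, rigid_traj, toy_structure):
        f = rigid_traj[7]
        L = angular_momentum(f, toy_structure)
        J = inertia_tensor(f, toy_structure)
        np.testing.assert_allclose(L, J @ OMEGA, atol=1e-14)

    def test_pure_drift_zero(self, toy_structure):
        u = np.array([0.1, 0.2, 0.3])
        f = Frame(
            time=0,
            positions=toy_structure.positions,
            velocities=np.tile(u, (toy_structure.n_beads, 1)),
        )
        np.testing.assert_allclose(angular_momentum(f, toy_structure), 0.0, atol=1e-13)


class TestApparentAngularVelocity:
    def test_rigid_recovery(self, rigid_traj, toy_structure):
        for f in rigid_traj:
            omega = apparent_angular_velocity(f, toy_structure)
            assert np.linalg.norm(omega - OMEGA) < 1e-10 * np.linalg.norm(OMEGA)

    def test_shear_lattice_half_ratio(self):
        gamma_dot = 0.01
        structure, frame = make_shear_cloud(123, 1.0, gamma_dot, lattice=True)
        omega = apparent_angular_velocity(frame, structure)
        assert abs(omega[2]) / gamma_dot == pytest.approx(0.5, abs=1e-12)
        assert omega[2] < 0  # right-handed axes, v1 = gdot * x2

    def test_breathing_zero(self, breathing_traj, toy_structure):
        np.testing.assert_allclose(
            apparent_angular_velocity(breathing_traj[9], toy_structure),
            0.0,
            atol=1e-13,
        )

    def test_collinear_degenerate_flagged(self):
        pos = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]], dtype=float)
        vel = np.zeros_like(pos)
        s = Structure(positions=pos, masses=np.ones(4))
        f = Frame(time=0, positions=pos, velocities=vel)
        state = lab_rotation_state(f, s)
        assert state.degenerate


class TestEckartRotation:
    def test_identity_on_reference(self, toy_structure):
        f = Frame(time=0, positions=toy_structure.positions)
        R, residual, _ = eckart_rotation(f, toy_structure)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert residual < 1e-12

    def test_recovers_known_rotation(self, toy_structure):
        rng = np.random.default_rng(11)
        for _ in range(5):
            Q = random_rotation(rng)
            com = toy_structure.center_of_mass()
            pos = (toy_structure.positions - com) @ Q.T + com
            R, _, _ = eckart_rotation(Frame(time=0, positions=pos), toy_structure)
            np.testing.assert_allclose(R, Q, atol=1e-10)

    def test_residual_after_small_displacements(self, toy_structure):
        # direct check of |sum m c x rho| for perturbed frames
        rng = np.random.default_rng(4)
        pos = toy_structure.positions + 0.01 * rng.normal(
            size=toy_structure.positions.shape
        )
        R, residual, _ = eckart_rotation(Frame(time=0, positions=pos), toy_structure)
        m = toy_structure.masses
        c = toy_structure.centered_positions()
        com = m @ pos / toy_structure.total_mass
        rho = (pos - com) @ R - c
        direct = np.linalg.norm((m[:, None] * np.cross(c, rho)).sum(axis=0))
        assert direct < 1e-9
        assert residual == pytest.approx(direct, abs=1e-15)

    def test_rejects_collinear_reference(self):
        s = Structure(
            positions=[[0, 0, 0], [0, 0, 1]], masses=[1, 1]
        )
        with pytest.raises(ValueError):
            eckart_rotation(Frame(time=0, positions=s.positions), s)

    def test_brute_force_net_oracle(self, composite_traj, toy_structure):
        # independent oracle: the mass-weighted superposition objective over a
        # dense net of rotations around the closed-form solution is minimized
        # at the closed-form solution
        rng = np.random.default_rng(99)
        m = toy_structure.masses
        c = toy_structure.centered_positions()
        for f in composite_traj.frames[::50]:
            R, _, _ = eckart_rotation(f, toy_structure)
            com = m @ f.positions / toy_structure.total_mass
            rel = f.positions - com

            def objective(rot):
                diff = rel - c @ rot.T
                return (m * (diff * diff).sum(axis=1)).sum()

            base = objective(R)
            for _ in range(200):
                assert objective(R @ random_rotation(rng, max_angle=0.5)) >= base


class TestEckartAngularVelocity:
    def test_rigid_rotor_exact(self, rigid_traj, toy_structure):
        for f in rigid_traj:
            st_ = eckart_angular_velocity(f, toy_structure)
            assert np.linalg.norm(st_.Omega - OMEGA) < 1e-10 * np.linalg.norm(OMEGA)
            np.testing.assert_allclose(st_.delta_v, 0.0, atol=1e-13)

    def test_breathing_no_rotation_no_angular_part(
        self, breathing_traj, toy_structure
    ):
        for f in breathing_traj.frames[::10]:
            st_ = eckart_angular_velocity(f, toy_structure)
            np.testing.assert_allclose(st_.Omega, 0.0, atol=1e-13)
            np.testing.assert_allclose(st_.v_ang, 0.0, atol=1e-13)

    def test_composite_time_averaged_tracking(self, composite_traj, toy_structure):
        # Eckart mean angular velocity recovers the prescribed rotation far
        # better than the lab mean (which rectifies the twist contamination)
        o3 = []
        O3 = []
        for f in composite_traj:
            st_ = eckart_angular_velocity(f, toy_structure)
            o3.append(st_.omega_lab[2])
            O3.append(st_.Omega[2])
        err_lab = abs(np.mean(o3) - OMEGA3)
        err_eck = abs(np.mean(O3) - OMEGA3)
        assert err_eck < err_lab

    def test_omega_decomposition_identity(self, any_fixture_traj):
        # omega_lab = Omega + Omega_vib, exactly
        ref = any_fixture_traj.structure
        for f in any_fixture_traj.frames[::10]:
            st_ = eckart_angular_velocity(f, ref)
            np.testing.assert_allclose(
                st_.omega_lab, st_.Omega + st_.Omega_vib, atol=1e-12
            )

    def test_velocity_split_consistency(self, composite_traj, toy_structure):
        for f in composite_traj.frames[::25]:
            st_ = eckart_angular_velocity(f, toy_structure)
            np.testing.assert_allclose(
                st_.delta_v, st_.v_nonang + st_.v_ang, atol=1e-14
            )
            # v_nonang carries no angular momentum about the COM
            m = toy_structure.masses
            rel = f.positions - st_.com
            L_nonang = (m[:, None] * np.cross(rel, st_.v_nonang)).sum(axis=0)
            np.testing.assert_allclose(L_nonang, 0.0, atol=1e-12)


class TestInvariants:
    def test_rotation_orthogonality(self, any_fixture_traj):
        ref = any_fixture_traj.structure
        for f in any_fixture_traj.frames[::10]:
            st_ = eckart_angular_velocity(f, ref)
            R = st_.rotation
            assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
            assert np.linalg.det(R) > 0

    def test_eckart_residual(self, any_fixture_traj):
        ref = any_fixture_traj.structure
        for f in any_fixture_traj.frames[::10]:
            st_ = eckart_angular_velocity(f, ref)
            assert st_.eckart_residual < 1e-9

    def test_coriolis_minimization_under_perturbations(
        self, composite_traj, toy_structure
    ):
        rng = np.random.default_rng(17)
        max_angle = np.deg2rad(5.0)
        for f in composite_traj.frames[::25]:
            st_ = eckart_angular_velocity(f, toy_structure)
            base = np.linalg.norm(coriolis_coupling_vector(st_))
            for _ in range(100):
                Q = random_rotation(rng, max_angle=max_angle)
                perturbed = np.linalg.norm(coriolis_coupling_vector(st_, Q))
                assert perturbed + 1e-12 >= base

    def test_frame_convention_invariance(self, composite_traj, toy_structure):
        # rotating the whole lab trajectory by Q maps omega -> Q omega and
        # Omega -> Q Omega
        rng = np.random.default_rng(23)
        Q = random_rotation(rng)
        f = composite_traj[40]
        st0 = eckart_angular_velocity(f, toy_structure)
        f_rot = Frame(
            time=f.time,
            positions=f.positions @ Q.T,
            velocities=f.velocities @ Q.T,
        )
        st1 = eckart_angular_velocity(f_rot, toy_structure)
        np.testing.assert_allclose(st1.omega_lab, Q @ st0.omega_lab, atol=1e-12)
        np.testing.assert_allclose(st1.Omega, Q @ st0.Omega, atol=1e-12)


class TestFiniteDifference:
    def _drift_traj(self, toy_structure, n, dt):
        u = np.array([0.1, -0.05, 0.02])
        frames = [
            Frame(time=i * dt, positions=toy_structure.positions + u * i * dt)
            for i in range(n)
        ]
        return Trajectory(toy_structure, tuple(frames), dt=dt)

    def test_linear_drift_exact(self, toy_structure):
        traj = finite_difference_velocities(self._drift_traj(toy_structure, 5, DT))
        for f in traj:
            np.testing.assert_allclose(
                f.velocities, np.tile([0.1, -0.05, 0.02], (toy_structure.n_beads, 1)),
                atol=1e-12,
            )

    def test_static_zero(self, toy_structure):
        frames = [
            Frame(time=i * DT, positions=toy_structure.positions) for i in range(4)
        ]
        traj = finite_difference_velocities(
            Trajectory(toy_structure, tuple(frames), dt=DT)
        )
        for f in traj:
            np.testing.assert_allclose(f.velocities, 0.0, atol=1e-15)

    def test_second_order_convergence(self, toy_structure):
        # halving dt reduces the interior central-difference error ~4x
        def max_err(dt):
            exact = make_rigid_rotor(toy_structure, OMEGA * 40, 9, dt)
            stripped = Trajectory(
                toy_structure,
                tuple(Frame(time=f.time, positions=f.positions) for f in exact),
                dt=dt,
            )
            fd = finite_difference_velocities(stripped)
            errs = [
                np.abs(fd[i].velocities - exact[i].velocities).max()
                for i in range(1, 8)
            ]
            return max(errs)

        ratio = max_err(0.4) / max_err(0.2)
        assert 3.5 < ratio < 4.5

    def test_rejects_nonuniform_grid(self, toy_structure):
        frames = [
            Frame(time=t, positions=toy_structure.positions)
            for t in (0.0, 0.1, 0.35)
        ]
        with pytest.raises(ValueError):
            finite_difference_velocities(Trajectory(toy_structure, tuple(frames)))
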