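"""Laboratory-frame and Eckart-frame angular velocity of a flexible bead set.

The laboratory (apparent) angular velocity solves ``J w = L`` with the
instantaneous inertia tensor and angular momentum about the center of mass;
for a flexible body it mixes pure rotation with vibrations carrying angular
momentum.

The Eckart frame is anchored to a reference configuration ``c_alpha``
(mass-centered).  Its per-frame orientation ``R`` is the mass-weighted
optimal superposition of the reference onto the instantaneous positions,
which satisfies the Eckart condition

    sum_alpha m_alpha c_alpha x rho_alpha = 0,

where ``rho_alpha = R^T (r_alpha - r_cm) - c_alpha``.  Differentiating that
condition in time yields the frame ("pure") angular velocity in body axes,

    J' w_b = sum_alpha m_alpha c_alpha x [R^T (v_alpha - v_cm)],
    J'     = sum_alpha m_alpha [(c_alpha . s_alpha) I - s_alpha c_alpha^T],

with ``s_alpha = c_alpha + rho_alpha``; ``Omega = R w_b`` in lab axes.  The
remaining velocity ``dv = (v - v_cm) - Omega x (r - r_cm)`` is split into an
angular-momentum-free part ``v~`` and an angular part ``u = Omega_v x
(r - r_cm)`` with ``Omega_v = J^{-1} sum m (r - r_cm) x dv``.  This gauge
gives the exact identity ``omega_lab = Omega + Omega_v``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Frame, Structure, Trajectory

__all__ = [
    "LabRotationState",
    "EckartState",
    "center_of_mass",
    "inertia_tensor",
    "angular_momentum",
    "apparent_angular_velocity",
    "lab_rotation_state",
    "eckart_rotation",
    "eckart_angular_velocity",
    "coriolis_coupling_vector",
    "finite_difference_velocities",
]

#: relative condition-number threshold beyond which an inertia solve is
#: treated as degenerate and falls back to the pseudo-inverse
_DEGENERACY_RCOND = 1e-12

ORTHOGONALITY_TOL = 1e-10
ECKART_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class LabRotationState:
    """Apparent (laboratory-frame) rotation state of one frame."""

    com: np.ndarray
    com_velocity: np.ndarray
    inertia: np.ndarray
    angular_momentum: np.ndarray
    omega: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True, eq=False)
class EckartState:
    """Eckart corotating-frame state of one frame.

    ``rotation`` maps reference (body) axes to lab axes; ``rho`` is stored in
    body axes while ``delta_v``, ``v_nonang`` and ``v_ang`` are stored in lab
    axes (rotate by ``rotation.T`` for body-axis components).
    """

    rotation: np.ndarray
    reference: Structure
    rho: np.ndarray
    eckart_inertia: np.ndarray
    Omega: np.ndarray
    Omega_vib: np.ndarray
    omega_lab: np.ndarray
    inertia: np.ndarray
    com: np.ndarray
    com_velocity: np.ndarray
    delta_v: np.ndarray
    v_nonang: np.ndarray
    v_ang: np.ndarray
    eckart_residual: float
    degenerate: bool = False


def _solve_spd(matrix: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve ``matrix @ x = rhs``; pseudo-inverse + flag when near-singular."""
    svals = np.linalg.svd(matrix, compute_uv=False)
    if svals[0] == 0 or svals[-1] / svals[0] < _DEGENERACY_RCOND:
        return np.linalg.pinv(matrix, rcond=_DEGENERACY_RCOND) @ rhs, True
    return np.linalg.solve(matrix, rhs), False


def center_of_mass(frame: Frame, structure: Structure) -> tuple[np.ndarray, np.ndarray | None]:
    """Mass-weighted mean position and (when available) velocity."""
    m = structure.masses
    total = structure.total_mass
    com = m @ frame.positions / total
    vcm = m @ frame.velocities / total if frame.has_velocities else None
    return com, vcm


def inertia_tensor(frame: Frame, structure: Structure) -> np.ndarray:
    """J = sum m [(r-r_cm).(r-r_cm) I - (r-r_cm)(r-r_cm)^T]."""
    m = structure.masses
    com = m @ frame.positions / structure.total_mass
    rel = frame.positions - com
    r2 = (m * (rel * rel).sum(axis=1)).sum()
    return r2 * np.eye(3) - (m[:, None] * rel).T @ rel


def angular_momentum(frame: Frame, structure: Structure) -> np.ndarray:
    """L = sum m (r - r_cm) x (v - v_cm)."""
    vel = frame.require_velocities()
    m = structure.masses
    com = m @ frame.positions / structure.total_mass
    vcm = m @ vel / structure.total_mass
    return (m[:, None] * np.cross(frame.positions - com, vel - vcm)).sum(axis=0)


def lab_rotation_state(frame: Frame, structure: Structure) -> LabRotationState:
    com, vcm = center_of_mass(frame, structure)
    if vcm is None:
        raise ValueError("laboratory rotation state requires velocities")
    inertia = inertia_tensor(frame, structure)
    L = angular_momentum(frame, structure)
    omega, degenerate = _solve_spd(inertia, L)
    return LabRotationState(
        com=com,
        com_velocity=vcm,
        inertia=inertia,
        angular_momentum=L,
        omega=omega,
        degenerate=degenerate,
    )


def apparent_angular_velocity(frame: Frame, structure: Structure) -> np.ndarray:
    """Angular velocity solving ``J w = L`` (pseudo-inverse when degenerate)."""
    return lab_rotation_state(frame, structure).omega


def eckart_rotation(
    frame: Frame, reference: Structure
) -> tuple[np.ndarray, float, bool]:
    """Proper rotation of the Eckart frame plus condition residual.

    Returns ``(R, residual, degenerate)`` where ``R`` maps reference axes to
    lab axes, ``residual = |sum m c x rho|`` (amu nm^2) and ``degenerate``
    flags a non-unique optimum (collinear or planar-degenerate reference).
    """
    if frame.n_beads != reference.n_beads:
        raise ValueError("frame and reference bead counts differ")
    if reference.n_beads < 3:
        raise ValueError("Eckart rotation needs at least 3 beads")
    m = reference.masses
    c = reference.centered_positions()
    com = m @ frame.positions / reference.total_mass
    rel = frame.positions - com
    degenerate = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, _ = Rotation.align_vectors(rel, c, weights=m)
        for w in caught:
            if "Optimal rotation is not uniquely" in str(w.message):
                degenerate = True
    R = rot.as_matrix()
    rho = rel @ R - c  # R^T applied row-wise
    residual = float(np.linalg.norm((m[:, None] * np.cross(c, rho)).sum(axis=0)))
    return R, residual, degenerate


def eckart_angular_velocity(frame: Frame, reference: Structure) -> EckartState:
    """Full Eckart-frame state for one frame (see module docstring)."""
    vel = frame.require_velocities()
    m = reference.masses
    total = reference.total_mass
    c = reference.centered_positions()
    R, residual, degenerate_rot = eckart_rotation(frame, reference)
    com = m @ frame.positions / total
    vcm = m @ vel / total
    rel = frame.positions - com
    vrel = vel - vcm
    s = rel @ R  # body-axis instantaneous positions
    rho = s - c
    vprime = vrel @ R  # body-axis velocities
    # J' = sum m [(c.s) I - s c^T]
    cs = (m * (c * s).sum(axis=1)).sum()
    eckart_inertia = cs * np.eye(3) - (m[:, None] * s).T @ c
    rhs = (m[:, None] * np.cross(c, vprime)).sum(axis=0)
    omega_body, degenerate_jp = _solve_spd(eckart_inertia, rhs)
    Omega = R @ omega_body

    inertia = inertia_tensor(frame, reference)
    L = (m[:, None] * np.cross(rel, vrel)).sum(axis=0)
    omega_lab, degenerate_j = _solve_spd(inertia, L)

    delta_v = vrel - np.cross(Omega, rel)
    L_vib = (m[:, None] * np.cross(rel, delta_v)).sum(axis=0)
    Omega_vib, degenerate_v = _solve_spd(inertia, L_vib)
    v_ang = np.cross(Omega_vib, rel)
    v_nonang = delta_v - v_ang

    return EckartState(
        rotation=R,
        reference=reference,
        rho=rho,
        eckart_inertia=eckart_inertia,
        Omega=Omega,
        Omega_vib=Omega_vib,
        omega_lab=omega_lab,
        inertia=inertia,
        com=com,
        com_velocity=vcm,
        delta_v=delta_v,
        v_nonang=v_nonang,
        v_ang=v_ang,
        eckart_residual=residual,
        degenerate=degenerate_rot or degenerate_jp or degenerate_j or degenerate_v,
    )


def coriolis_coupling_vector(
    state: EckartState, body_perturbation: np.ndarray | None = None
) -> np.ndarray:
    """First-order Coriolis coupling sum ``sum m (Q c) x (R^T dv)``.

    With ``body_perturbation = Q = I`` (the Eckart frame itself) this is the
    time derivative of the Eckart condition and vanishes to solver precision;
    any fixed body-axis relabeling ``Q != I`` leaves the physical frame
    rotation rate unchanged but produces a nonzero coupling, which is the
    sense in which the Eckart frame minimizes the Coriolis coupling.
    """
    m = state.reference.masses
    c = state.reference.centered_positions()
    if body_perturbation is not None:
        c = c @ np.asarray(body_perturbation).T
    dv_body = state.delta_v @ state.rotation
    return (m[:, None] * np.cross(c, dv_body)).sum(axis=0)


def finite_difference_velocities(trajectory: Trajectory) -> Trajectory:
    """Central-difference velocities (one-sided at the ends), uniform grid only."""
    if len(trajectory) < 3:
        raise ValueError("finite differencing needs at least 3 frames")
    times = trajectory.times
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("finite differencing requires a uniform time grid")
    dt = steps[0]
    pos = np.array([f.positions for f in trajectory])
    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2 * dt)
    vel[0] = (pos[1] - pos[0]) / dt
    vel[-1] = (pos[-1] - pos[-2]) / dt
    frames = [
        Frame(time=t, positions=p, velocities=v)
        for t, p, v in zip(times, pos, vel)
    ]
    return Trajectory(
        trajectory.structure, tuple(frames), dt=trajectory.dt, motion=trajectory.motion
    )
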