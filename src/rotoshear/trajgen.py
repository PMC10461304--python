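"""Synthetic trajectory generators with analytically known motion content.

Every generator produces velocities in closed form (no finite differencing),
so downstream angular-velocity and kinetic-energy results can be checked
against exact ground truth.  All quantities use the amu/nm/ps unit system.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Frame, MotionSpec, Structure, Trajectory

__all__ = [
    "make_rigid_rotor",
    "make_breathing",
    "make_twist",
    "make_shear_cloud",
    "compose",
    "make_toy_protein",
]


def _time_grid(n_frames: int, dt: float) -> np.ndarray:
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.arange(n_frames) * dt


def make_rigid_rotor(
    structure: Structure,
    omega: np.ndarray,
    n_frames: int,
    dt: float,
) -> Trajectory:
    """Rigid rotation of ``structure`` about its center of mass.

    ``omega`` is the constant angular velocity vector in 1/ps.  Frame ``t``
    carries positions ``r_cm + R(t) c_alpha`` with ``R(t)`` the rotation by
    ``|omega| t`` about the omega axis, and exact velocities
    ``omega x (r - r_cm)``; the center of mass stays at rest.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (3,) or not np.all(np.isfinite(omega)):
        raise ValueError("omega must be a finite 3-vector")
    times = _time_grid(n_frames, dt)
    com = structure.center_of_mass()
    c = structure.centered_positions()
    frames = []
    for t in times:
        rot = Rotation.from_rotvec(omega * t)
        pos = com + rot.apply(c)
        vel = np.cross(omega, pos - com)
        frames.append(Frame(time=t, positions=pos, velocities=vel))
    motion = MotionSpec(omega=tuple(omega), parts=("rigid",))
    return Trajectory(structure, tuple(frames), dt=dt, motion=motion)


def make_breathing(
    structure: Structure,
    amplitude: float,
    frequency: float,
    n_frames: int,
    dt: float,
) -> Trajectory:
    """Radial breathing mode: zero angular momentum in every frame.

    Positions are ``r_cm + (1 + a sin(2 pi f t)) c_alpha``; velocities are
    purely radial, so ``sum m (r - r_cm) x (v - v_cm)`` vanishes identically.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1) to avoid inversion")
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    times = _time_grid(n_frames, dt)
    com = structure.center_of_mass()
    c = structure.centered_positions()
    w = 2.0 * np.pi * frequency
    frames = []
    for t in times:
        scale = 1.0 + amplitude * np.sin(w * t)
        rate = amplitude * w * np.cos(w * t)
        frames.append(
            Frame(time=t, positions=com + scale * c, velocities=rate * c)
        )
    motion = MotionSpec(
        breathing_amplitude=amplitude, mode_frequency=frequency, parts=("breathing",)
    )
    return Trajectory(structure, tuple(frames), dt=dt, motion=motion)


def _split_halves(c: np.ndarray, axis: np.ndarray, tol: float = 1e-9):
    proj = c @ axis
    return proj > tol, proj < -tol


def make_twist(
    structure: Structure,
    twist_amplitude: float,
    frequency: float,
    axis: np.ndarray,
    n_frames: int,
    dt: float,
) -> Trajectory:
    """Counter-oscillating azimuthal twist of the two molecular halves.

    Beads are split by the sign of their reference coordinate along ``axis``
    (beads on the dividing plane stay put).  The two halves rotate by
    ``+theta(t)`` and ``-theta(t)`` with ``theta = A sin(2 pi f t)``, so the
    time-averaged rotation is zero while the instantaneous total angular
    momentum is generally nonzero: this is vibrational angular momentum.
    """
    if structure.n_beads < 2:
        raise ValueError("twist needs at least 2 beads")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be nonzero")
    if twist_amplitude < 0 or frequency < 0:
        raise ValueError("twist_amplitude and frequency must be >= 0")
    axis = axis / norm
    times = _time_grid(n_frames, dt)
    com = structure.center_of_mass()
    c = structure.centered_positions()
    upper, lower = _split_halves(c, axis)
    w = 2.0 * np.pi * frequency
    frames = []
    for t in times:
        theta = twist_amplitude * np.sin(w * t)
        theta_dot = twist_amplitude * w * np.cos(w * t)
        pos = c.copy()
        pos[upper] = Rotation.from_rotvec(axis * theta).apply(c[upper])
        pos[lower] = Rotation.from_rotvec(-axis * theta).apply(c[lower])
        vel = np.zeros_like(c)
        vel[upper] = theta_dot * np.cross(axis, pos[upper])
        vel[lower] = -theta_dot * np.cross(axis, pos[lower])
        frames.append(Frame(time=t, positions=com + pos, velocities=vel))
    motion = MotionSpec(
        twist_amplitude=twist_amplitude, mode_frequency=frequency, parts=("twist",)
    )
    return Trajectory(structure, tuple(frames), dt=dt, motion=motion)


def make_shear_cloud(
    n_beads: int,
    radius: float,
    gamma_dot: float,
    lattice: bool = True,
    seed: int | None = None,
    mass: float = 1.0,
) -> tuple[Structure, Frame]:
    """Spherical bead cloud sampled by the linear shear profile v1 = gdot x2.

    With ``lattice=True`` the beads sit on the smallest simple-cubic ball with
    at least ``n_beads`` sites.  That point set is exactly closed under
    coordinate permutations and sign flips, so second moments along all axes
    are identical and the downstream apparent angular velocity obeys
    ``|omega_3| = gamma_dot / 2`` analytically.  ``gamma_dot`` is in 1/ps.
    """
    if n_beads < 4:
        raise ValueError("n_beads must be >= 4")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if lattice:
        k = 1
        while True:
            rng_idx = np.arange(-k, k + 1)
            grid = np.array(np.meshgrid(rng_idx, rng_idx, rng_idx)).reshape(3, -1).T
            keep = (grid**2).sum(axis=1) <= k * k
            pts = grid[keep] * (radius / k)
            if pts.shape[0] >= n_beads:
                break
            k += 1
        positions = pts.astype(float)
    else:
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n_beads:
            cand = rng.uniform(-radius, radius, size=(2 * n_beads, 3))
            out.extend(cand[np.linalg.norm(cand, axis=1) <= radius])
        positions = np.array(out[:n_beads])
        positions -= positions.mean(axis=0)  # re-center; symmetry only statistical
    n = positions.shape[0]
    structure = Structure(positions=positions, masses=np.full(n, float(mass)))
    velocities = np.zeros_like(positions)
    velocities[:, 0] = gamma_dot * positions[:, 1]
    frame = Frame(time=0.0, positions=positions, velocities=velocities)
    return structure, frame


def _merge_motion(parts: list[Trajectory], com_velocity: np.ndarray) -> MotionSpec:
    omega = (0.0, 0.0, 0.0)
    breathing = 0.0
    twist = 0.0
    freq = 0.0
    names: list[str] = []
    for p in parts:
        m = p.motion
        if m is None:
            continue
        names.extend(m.parts)
        if any(m.omega) and not any(omega):
            omega = m.omega
        if m.breathing_amplitude and not breathing:
            breathing = m.breathing_amplitude
        if m.twist_amplitude and not twist:
            twist = m.twist_amplitude
        if m.mode_frequency and not freq:
            freq = m.mode_frequency
    return MotionSpec(
        omega=omega,
        breathing_amplitude=breathing,
        twist_amplitude=twist,
        mode_frequency=freq,
        com_velocity=tuple(com_velocity),
        parts=tuple(names),
    )


def compose(
    parts: list[Trajectory],
    com_velocity: np.ndarray = (0.0, 0.0, 0.0),
) -> Trajectory:
    """Superpose displacement fields of trajectories sharing one structure.

    Frame-by-frame, displacements from the shared reference positions and the
    velocities are summed, and a uniform center-of-mass drift is added.  The
    merged ground-truth MotionSpec is recorded on the result.
    """
    if not parts:
        raise ValueError("compose needs at least one trajectory")
    com_velocity = np.asarray(com_velocity, dtype=float)
    base = parts[0]
    ref = base.structure.positions
    times = base.times
    for p in parts[1:]:
        if p.structure.n_beads != base.structure.n_beads or not np.allclose(
            p.structure.positions, ref, atol=1e-12
        ):
            raise ValueError("all parts must share an identical structure")
        if len(p) != len(base) or not np.allclose(p.times, times, atol=1e-12):
            raise ValueError("all parts must share an identical time grid")
    frames = []
    for i, t in enumerate(times):
        disp = np.zeros_like(ref)
        vel = np.zeros_like(ref)
        for p in parts:
            disp += p[i].positions - ref
            vel += p[i].require_velocities()
        pos = ref + disp + com_velocity * t
        frames.append(Frame(time=t, positions=pos, velocities=vel + com_velocity))
    return Trajectory(
        base.structure,
        tuple(frames),
        dt=base.dt,
        motion=_merge_motion(parts, com_velocity),
    )


def make_toy_protein(
    n_beads: int,
    bond_length: float = 0.35,
    seed: int | None = None,
    mass: float = 1.0,
    min_separation_factor: float = 0.9,
    candidates_per_step: int = 40,
    max_restarts: int = 50,
) -> Structure:
    """Self-avoiding compact bead chain with fixed consecutive spacing.

    Grows the chain one bead at a time; at each step the candidate direction
    closest to the running centroid that keeps every pairwise distance at
    least ``min_separation_factor * bond_length`` is taken.  Deterministic
    for a fixed seed.
    """
    if n_beads < 3:
        raise ValueError("n_beads must be >= 3")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    rng = np.random.default_rng(seed)
    min_sep = min_separation_factor * bond_length
    for _ in range(max_restarts):
        beads = [np.zeros(3), np.array([bond_length, 0.0, 0.0])]
        failed = False
        while len(beads) < n_beads:
            arr = np.asarray(beads)
            centroid = arr.mean(axis=0)
            dirs = rng.normal(size=(candidates_per_step, 3))
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
            cands = beads[-1] + bond_length * dirs
            dists = np.linalg.norm(cands[:, None, :] - arr[None, :-1, :], axis=2)
            ok = dists.min(axis=1) >= min_sep
            if not ok.any():
                failed = True
                break
            good = cands[ok]
            beads.append(good[np.argmin(np.linalg.norm(good - centroid, axis=1))])
        if not failed:
            return Structure(
                positions=np.asarray(beads), masses=np.full(n_beads, float(mass))
            )
    raise RuntimeError(
        f"could not pack {n_beads} beads after {max_restarts} restarts"
    )
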