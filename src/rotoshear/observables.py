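"""Conformational observables: gyration tensor, Rg, RMSD, RMSF.

All observables are mass-weighted by default (toggle with ``mass_weighted``)
and, when superposition is requested, use the same mass-weighted optimal
rotation that defines the Eckart frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Structure, Trajectory
from .eckart import eckart_rotation

__all__ = [
    "GyrationResult",
    "gyration_tensor",
    "rg_timeseries",
    "normalized_diagonals",
    "rmsd",
    "rmsf",
    "superpose_positions",
]


@dataclass(frozen=True, eq=False)
class GyrationResult:
    tensor: np.ndarray  # nm^2, symmetric PSD
    rg: float  # nm, sqrt(trace)
    diagonal_ratios: np.ndarray | None = None


def _weights(structure: Structure, mass_weighted: bool) -> np.ndarray:
    if mass_weighted:
        return structure.masses / structure.total_mass
    n = structure.n_beads
    return np.full(n, 1.0 / n)


def gyration_tensor(
    frame: Frame | np.ndarray,
    structure: Structure,
    mass_weighted: bool = True,
) -> GyrationResult:
    """G_mu_nu = sum_a w_a (r_a - r_c)_mu (r_a - r_c)_nu with w the bead weights."""
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame, float)
    w = _weights(structure, mass_weighted)
    center = w @ pos
    rel = pos - center
    tensor = (w[:, None] * rel).T @ rel
    return GyrationResult(tensor=tensor, rg=float(np.sqrt(np.trace(tensor))))


def rg_timeseries(
    trajectory: Trajectory, mass_weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (time, rg) arrays."""
    times = trajectory.times
    rgs = np.array(
        [
            gyration_tensor(f, trajectory.structure, mass_weighted).rg
            for f in trajectory
        ]
    )
    return times, rgs


def normalized_diagonals(
    trajectory: Trajectory,
    reference_trajectory: Trajectory,
    mass_weighted: bool = True,
) -> np.ndarray:
    """<G_ii> of ``trajectory`` over <G_ii> of the zero-shear reference, i=1,2,3."""
    def mean_diag(traj: Trajectory) -> np.ndarray:
        return np.mean(
            [
                np.diag(gyration_tensor(f, traj.structure, mass_weighted).tensor)
                for f in traj
            ],
            axis=0,
        )

    num = mean_diag(trajectory)
    den = mean_diag(reference_trajectory)
    if np.any(den == 0):
        raise ZeroDivisionError("reference trajectory has a zero diagonal component")
    return num / den


def superpose_positions(
    positions: np.ndarray, reference: Structure
) -> np.ndarray:
    """Remove COM and rotate ``positions`` onto the reference (mass-weighted)."""
    frame = Frame(time=0.0, positions=positions)
    R, _, _ = eckart_rotation(frame, reference)
    m = reference.masses
    com = m @ positions / reference.total_mass
    return (positions - com) @ R + reference.center_of_mass()


def rmsd(
    frame: Frame | np.ndarray,
    reference: Structure,
    superpose: bool = True,
    mass_weighted: bool = True,
) -> float:
    """Root-mean-square deviation from the reference structure (nm)."""
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame, float)
    if pos.shape[0] != reference.n_beads:
        raise ValueError("bead count mismatch between frame and reference")
    if superpose:
        pos = superpose_positions(pos, reference)
    w = _weights(reference, mass_weighted)
    diff = pos - reference.positions
    return float(np.sqrt((w * (diff * diff).sum(axis=1)).sum()))


def rmsf(
    trajectory: Trajectory,
    reference: Structure | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-bead RMS fluctuation about the time-mean position (nm).

    Each frame is first superposed onto ``reference`` (default: the
    trajectory's structure); fluctuations are then taken about the
    time-averaged bead positions.
    """
    if len(trajectory) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    reference = reference if reference is not None else trajectory.structure
    stack = []
    for f in trajectory:
        pos = superpose_positions(f.positions, reference) if superpose else f.positions
        stack.append(pos)
    arr = np.asarray(stack)
    mean_pos = arr.mean(axis=0)
    return np.sqrt(((arr - mean_pos) ** 2).sum(axis=2).mean(axis=0))
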