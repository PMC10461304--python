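"""Core data containers for bead trajectories.

Unit system: lengths in nm, times in ps, masses in amu.  With these units
kinetic energies in amu nm^2 ps^-2 are numerically identical to kJ/mol and
angular velocities are per-ps (multiply by ``PS_TO_NS`` for the per-ns
convention used in reporting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PS_TO_NS",
    "DEFAULT_BEAD_MASS",
    "Structure",
    "Frame",
    "Trajectory",
    "MotionSpec",
]

#: angular velocity conversion factor: (1/ps) * PS_TO_NS = (1/ns)
PS_TO_NS = 1000.0

#: default mass of a coarse-grained bead (amu)
DEFAULT_BEAD_MASS = 72.0


def _as_vec_array(x, name: str, width: int = 3) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise ValueError(f"{name} must have shape (n, {width}), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True, eq=False)
class Structure:
    """Reference (equilibrium) bead configuration with masses.

    Parameters
    ----------
    positions : (n, 3) array
        Bead positions in nm.
    masses : (n,) array
        Bead masses in amu, all strictly positive.
    labels : sequence of str, optional
        Per-bead labels (used when serializing to GRO/PDB).
    """

    positions: np.ndarray
    masses: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = _as_vec_array(self.positions, "positions")
        masses = np.asarray(self.masses, dtype=float)
        if masses.ndim != 1 or masses.shape[0] != pos.shape[0]:
            raise ValueError("masses must be a 1-d array matching positions")
        if pos.shape[0] < 1:
            raise ValueError("Structure needs at least one bead")
        if not np.all(masses > 0):
            raise ValueError("all masses must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "masses", masses)
        if self.labels is not None:
            labels = tuple(str(s) for s in self.labels)
            if len(labels) != pos.shape[0]:
                raise ValueError("labels length must match bead count")
            object.__setattr__(self, "labels", labels)

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.positions / self.total_mass

    def centered_positions(self) -> np.ndarray:
        """Positions relative to the mass-weighted center (the c_alpha set)."""
        return self.positions - self.center_of_mass()


@dataclass(frozen=True, eq=False)
class Frame:
    """One trajectory frame: time (ps), positions and velocities (nm, nm/ps)."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = _as_vec_array(self.positions, "positions")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "time", float(self.time))
        if self.velocities is not None:
            vel = _as_vec_array(self.velocities, "velocities")
            if vel.shape != pos.shape:
                raise ValueError("velocities shape must match positions")
            object.__setattr__(self, "velocities", vel)

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    def require_velocities(self) -> np.ndarray:
        if self.velocities is None:
            raise ValueError("frame has no velocities")
        return self.velocities


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth motion content recorded next to synthetic trajectories.

    ``omega`` is the prescribed rigid angular velocity in 1/ps (internal unit
    system); serialized sidecars carry explicit unit strings.
    """

    omega: tuple[float, float, float] = (0.0, 0.0, 0.0)
    breathing_amplitude: float = 0.0
    twist_amplitude: float = 0.0
    mode_frequency: float = 0.0
    com_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int | None = None
    parts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode_frequency < 0:
            raise ValueError("mode_frequency must be >= 0")
        if self.breathing_amplitude < 0 or self.twist_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    def to_json(self) -> str:
        payload = {
            "omega": list(self.omega),
            "omega_units": "1/ps",
            "breathing_amplitude": self.breathing_amplitude,
            "twist_amplitude": self.twist_amplitude,
            "twist_amplitude_units": "rad",
            "mode_frequency": self.mode_frequency,
            "mode_frequency_units": "1/ps",
            "com_velocity": list(self.com_velocity),
            "com_velocity_units": "nm/ps",
            "seed": self.seed,
            "parts": list(self.parts),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MotionSpec":
        d = json.loads(text)
        return cls(
            omega=tuple(d.get("omega", (0.0, 0.0, 0.0))),
            breathing_amplitude=float(d.get("breathing_amplitude", 0.0)),
            twist_amplitude=float(d.get("twist_amplitude", 0.0)),
            mode_frequency=float(d.get("mode_frequency", 0.0)),
            com_velocity=tuple(d.get("com_velocity", (0.0, 0.0, 0.0))),
            seed=d.get("seed"),
            parts=tuple(d.get("parts", ())),
        )


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Ordered frames sharing one Structure (masses + reference positions)."""

    structure: Structure
    frames: tuple[Frame, ...]
    dt: float | None = None
    motion: MotionSpec | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("Trajectory needs at least one frame")
        n = self.structure.n_beads
        for f in frames:
            if f.n_beads != n:
                raise ValueError("frame bead count does not match structure")
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.dt is not None:
            if self.dt <= 0:
                raise ValueError("dt must be positive")
            if len(times) > 1 and not np.allclose(
                np.diff(times), self.dt, rtol=1e-9, atol=1e-12
            ):
                raise ValueError("frame spacing does not match dt")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def has_velocities(self) -> bool:
        return all(f.has_velocities for f in self.frames)

    def with_frames(self, frames: Sequence[Frame]) -> "Trajectory":
        return Trajectory(self.structure, tuple(frames), dt=self.dt, motion=self.motion)
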