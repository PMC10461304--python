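"""Breakable elastic network over coarse-grained beads.

Bonds are built between bead pairs whose reference separation falls inside a
distance window, each with a harmonic potential ``1/2 k (r - r0)^2``.  Along
a trajectory a bond breaks irreversibly the first time its instantaneous
length exceeds its cutoff ``Rc``; broken pairs contribute no harmonic energy
(they are handed over to nonbonded treatment, which is outside this
package's scope).  Breaking is evaluated at the sampled frames only — an
analysis-resolution approximation of the per-step rule used in dynamics.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import Frame, Structure, Trajectory

__all__ = [
    "ENBond",
    "ElasticNetwork",
    "BreakEvent",
    "build_en",
    "assign_break_cutoffs",
    "apply_breaking",
    "harmonic_energy",
    "network_to_json",
    "network_from_json",
    "network_to_table",
    "events_to_csv",
]

DEFAULT_LOWER = 0.5  # nm
DEFAULT_UPPER = 0.9  # nm
DEFAULT_FORCE_CONSTANT = 550.0  # kJ mol^-1 nm^-2
DEFAULT_BREAK_MULTIPLIER = 1.35


@dataclass(frozen=True)
class ENBond:
    i: int
    j: int
    k: float
    r0: float
    Rc: float | None = None
    intact: bool = True
    break_time: float | None = None

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("bond requires i < j")
        if self.r0 <= 0 or self.k < 0:
            raise ValueError("bond needs r0 > 0 and k >= 0")
        if self.Rc is not None and self.Rc <= self.r0:
            raise ValueError("break cutoff Rc must exceed r0")
        if (self.break_time is not None) != (not self.intact):
            raise ValueError("break_time must be set iff the bond is broken")


@dataclass(frozen=True)
class BreakEvent:
    bond_index: int
    i: int
    j: int
    time: float
    length: float


@dataclass(frozen=True)
class ElasticNetwork:
    bonds: tuple[ENBond, ...]
    build_lower: float
    build_upper: float
    source_structure_id: str = ""

    def __post_init__(self) -> None:
        if not self.build_lower < self.build_upper:
            raise ValueError("build_lower must be < build_upper")
        pairs = [(b.i, b.j) for b in self.bonds]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate bond pairs")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_intact(self) -> int:
        return sum(b.intact for b in self.bonds)


def build_en(
    structure: Structure,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    k: float = DEFAULT_FORCE_CONSTANT,
    selection: Sequence[int] | None = None,
    source_structure_id: str = "",
) -> ElasticNetwork:
    """One bond per bead pair with ``lower <= |r_i - r_j| <= upper`` (nm).

    ``selection`` restricts the network to a bead subset (e.g. backbone
    beads); indices in the resulting bonds refer to the full structure.
    """
    if structure.n_beads < 2:
        raise ValueError("need at least 2 beads")
    idx = np.arange(structure.n_beads) if selection is None else np.asarray(selection)
    pos = structure.positions[idx]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    bonds = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if lower <= dist[a, b] <= upper:
                bonds.append(
                    ENBond(i=int(idx[a]), j=int(idx[b]), k=k, r0=float(dist[a, b]))
                )
    return ElasticNetwork(
        bonds=tuple(bonds),
        build_lower=lower,
        build_upper=upper,
        source_structure_id=source_structure_id,
    )


def assign_break_cutoffs(
    network: ElasticNetwork, multiplier: float = DEFAULT_BREAK_MULTIPLIER
) -> ElasticNetwork:
    """Set ``Rc = multiplier * r0`` on every bond (multiplier must exceed 1)."""
    if multiplier <= 1:
        raise ValueError("multiplier must be > 1 so that Rc > r0")
    bonds = tuple(replace(b, Rc=multiplier * b.r0) for b in network.bonds)
    return replace(network, bonds=bonds)


def _bond_lengths(network: ElasticNetwork, positions: np.ndarray) -> np.ndarray:
    ii = np.array([b.i for b in network.bonds], dtype=int)
    jj = np.array([b.j for b in network.bonds], dtype=int)
    if len(ii) and (ii.max() >= len(positions) or jj.max() >= len(positions)):
        raise IndexError("bond bead index out of range for frame")
    return np.linalg.norm(positions[ii] - positions[jj], axis=1)


def apply_breaking(
    network: ElasticNetwork, trajectory: Trajectory | Iterable[Frame]
) -> tuple[ElasticNetwork, list[BreakEvent], list[int]]:
    """Scan frames in order, breaking bonds irreversibly past their cutoff.

    Returns the final network, the break events (first crossing only), and
    the per-frame intact bond count (non-increasing by construction).
    """
    bonds = list(network.bonds)
    if any(b.Rc is None for b in bonds):
        raise ValueError("assign_break_cutoffs must be called first")
    events: list[BreakEvent] = []
    intact_counts: list[int] = []
    for frame in trajectory:
        lengths = _bond_lengths(network, frame.positions)
        for bi, bond in enumerate(bonds):
            if bond.intact and lengths[bi] > bond.Rc:
                bonds[bi] = replace(bond, intact=False, break_time=frame.time)
                events.append(
                    BreakEvent(
                        bond_index=bi,
                        i=bond.i,
                        j=bond.j,
                        time=frame.time,
                        length=float(lengths[bi]),
                    )
                )
        intact_counts.append(sum(b.intact for b in bonds))
    return replace(network, bonds=tuple(bonds)), events, intact_counts


def harmonic_energy(network: ElasticNetwork, frame: Frame) -> float:
    """Sum over intact bonds of 1/2 k (r - r0)^2, in kJ/mol."""
    if network.n_bonds == 0:
        return 0.0
    lengths = _bond_lengths(network, frame.positions)
    energy = 0.0
    for bond, r in zip(network.bonds, lengths):
        if bond.intact:
            energy += 0.5 * bond.k * (r - bond.r0) ** 2
    return float(energy)


def network_to_json(network: ElasticNetwork) -> str:
    return json.dumps(
        {
            "build_lower": network.build_lower,
            "build_upper": network.build_upper,
            "source_structure_id": network.source_structure_id,
            "bonds": [
                {
                    "i": b.i,
                    "j": b.j,
                    "k": b.k,
                    "r0": b.r0,
                    "Rc": b.Rc,
                    "intact": b.intact,
                    "break_time": b.break_time,
                }
                for b in network.bonds
            ],
        },
        indent=2,
    )


def network_from_json(text: str) -> ElasticNetwork:
    d = json.loads(text)
    return ElasticNetwork(
        bonds=tuple(ENBond(**b) for b in d["bonds"]),
        build_lower=d["build_lower"],
        build_upper=d["build_upper"],
        source_structure_id=d.get("source_structure_id", ""),
    )


def network_to_table(network: ElasticNetwork) -> str:
    """GROMACS-style bonded table: i j funct r0 k (1-based indices)."""
    lines = ["; i  j  funct  r0(nm)  k(kJ/mol/nm^2)"]
    for b in network.bonds:
        lines.append(f"{b.i + 1:6d} {b.j + 1:6d}  1  {b.r0:10.6f}  {b.k:10.3f}")
    return "\n".join(lines) + "\n"


def events_to_csv(events: list[BreakEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bond_index", "i", "j", "time_ps", "length_nm"])
        for e in events:
            writer.writerow([e.bond_index, e.i, e.j, e.time, e.length])
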