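"""Readers and writers: GRO (velocity columns), extended XYZ, PDB structures.

Internal coordinates are nm and ps.  PDB files (Angstrom) are converted on
read.  Bead masses are not part of the GRO/XYZ formats; they are assigned
from a per-label mass table with a configurable default (72 amu per
coarse-grained bead).  The extended-XYZ writer adds an explicit ``mass``
column so synthetic trajectories round-trip exactly.  Indexing is 0-based
internally and 1-based in GRO/PDB serializations.
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path

import numpy as np

from ..core import DEFAULT_BEAD_MASS, Frame, MotionSpec, Structure, Trajectory

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_gro",
    "read_gro_frames",
    "write_extxyz",
    "read_extxyz_frames",
    "write_motionspec",
    "read_motionspec",
    "backbone_bead_structure",
    "ubiquitin_backbone_structure",
]

#: standard atomic masses (amu) for PDB element lookup
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _masses_for_labels(
    labels: list[str],
    mass_map: dict[str, float] | None,
    default_mass: float | None,
) -> np.ndarray:
    mass_map = mass_map or {}
    masses = []
    for lab in labels:
        if lab in mass_map:
            masses.append(mass_map[lab])
        elif default_mass is not None:
            masses.append(default_mass)
        else:
            raise KeyError(
                f"no mass for bead label {lab!r} and no default mass configured"
            )
    return np.asarray(masses, float)


# ---------------------------------------------------------------------------
# GRO

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def write_gro(trajectory: Trajectory, path, resname: str = "BEAD") -> None:
    """Multi-frame GRO with velocity columns when present (fixed width)."""
    structure = trajectory.structure
    labels = structure.labels or tuple(
        f"B{i + 1}" for i in range(structure.n_beads)
    )
    with open(path, "w") as fh:
        for frame in trajectory:
            fh.write(f"rotoshear t= {frame.time:.6f}\n")
            fh.write(f"{frame.n_beads:5d}\n")
            vel = frame.velocities
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i]
                line = (
                    f"{i + 1:5d}{resname:<5.5s}{labels[i]:>5.5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                )
                if vel is not None:
                    line += f"{vel[i][0]:8.4f}{vel[i][1]:8.4f}{vel[i][2]:8.4f}"
                fh.write(line + "\n")
            fh.write("   0.00000   0.00000   0.00000\n")


def read_gro_frames(path) -> list[tuple[float | None, list[str], np.ndarray, np.ndarray | None]]:
    """Raw GRO frames: (time, labels, positions, velocities-or-None)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        title = lines[pos]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else None
        try:
            natoms = int(lines[pos + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ValueError(f"frame {frame_no}: malformed atom-count line") from exc
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"frame {frame_no}: truncated ({len(body)}/{natoms} atoms)")
        labels, xyz, vel = [], [], []
        has_vel = len(body[0].rstrip("\n")) >= 68
        for ln_no, line in enumerate(body, start=1):
            try:
                labels.append(line[10:15].strip())
                xyz.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
                if has_vel:
                    vel.append(
                        [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                    )
            except ValueError as exc:
                raise ValueError(
                    f"frame {frame_no}, atom line {ln_no}: malformed GRO record"
                ) from exc
        if pos + 2 + natoms >= len(lines):
            raise ValueError(f"frame {frame_no}: missing box line")
        frames.append(
            (
                time,
                labels,
                np.asarray(xyz, float),
                np.asarray(vel, float) if has_vel else None,
            )
        )
        pos += natoms + 3
    if not frames:
        raise ValueError("no frames found in GRO file")
    return frames


# ---------------------------------------------------------------------------
# extended XYZ

def write_extxyz(trajectory: Trajectory, path) -> None:
    """Extended XYZ with species, positions, optional velocities, and masses."""
    structure = trajectory.structure
    labels = structure.labels or tuple(
        f"B{i + 1}" for i in range(structure.n_beads)
    )
    with open(path, "w") as fh:
        for frame in trajectory:
            props = "species:S:1:pos:R:3"
            if frame.has_velocities:
                props += ":vel:R:3"
            props += ":mass:R:1"
            fh.write(f"{frame.n_beads}\n")
            fh.write(f'Time={frame.time:.10g} Properties={props}\n')
            for i in range(frame.n_beads):
                cols = [labels[i]]
                cols += [f"{v:.12g}" for v in frame.positions[i]]
                if frame.velocities is not None:
                    cols += [f"{v:.12g}" for v in frame.velocities[i]]
                cols.append(f"{structure.masses[i]:.12g}")
                fh.write(" ".join(cols) + "\n")


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    toks = spec.split(":")
    if len(toks) % 3:
        raise ValueError(f"malformed Properties spec: {spec!r}")
    return [(toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)]


def read_extxyz_frames(path):
    """Raw extended-XYZ frames: (time, labels, positions, velocities, masses)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_no}: bad atom count line {pos + 1}") from exc
        if pos + 1 >= len(lines):
            raise ValueError(f"frame {frame_no}: missing comment line")
        comment = lines[pos + 1]
        tm = re.search(r"\bTime=([-+0-9.eE]+)", comment)
        time = float(tm.group(1)) if tm else None
        pm = re.search(r'Properties=(\S+)', comment)
        props = _parse_properties(pm.group(1)) if pm else [
            ("species", "S", 1),
            ("pos", "R", 3),
        ]
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"frame {frame_no}: truncated ({len(body)}/{natoms} atoms)")
        labels, arrays = [], {name: [] for name, _, _ in props if name != "species"}
        for ln_no, line in enumerate(body, start=1):
            toks = line.split()
            expected = sum(w for _, _, w in props)
            if len(toks) != expected:
                raise ValueError(
                    f"frame {frame_no}, line {ln_no}: expected {expected} columns"
                )
            cursor = 0
            for name, kind, width in props:
                chunk = toks[cursor : cursor + width]
                cursor += width
                if name == "species":
                    labels.append(chunk[0])
                else:
                    arrays[name].append([float(v) for v in chunk])
        positions = np.asarray(arrays.get("pos", []), float)
        velocities = (
            np.asarray(arrays["vel"], float) if "vel" in arrays else None
        )
        masses = (
            np.asarray(arrays["mass"], float).ravel() if "mass" in arrays else None
        )
        frames.append((time, labels, positions, velocities, masses))
        pos += natoms + 2
    if not frames:
        raise ValueError("no frames found in extended-XYZ file")
    return frames


# ---------------------------------------------------------------------------
# high-level API

def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"gro", "pdb"}:
        return suffix
    if suffix in {"xyz", "extxyz"}:
        return "xyz"
    raise ValueError(f"cannot infer format from {path}")


def read_structure(
    path,
    fmt: str | None = None,
    mass_map: dict[str, float] | None = None,
    default_mass: float | None = DEFAULT_BEAD_MASS,
) -> Structure:
    """Read a single-frame structure from GRO, PDB, or (extended) XYZ."""
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        return _read_pdb_structure(path, mass_map=mass_map, default_mass=default_mass)
    if fmt == "gro":
        _, labels, positions, _ = read_gro_frames(path)[0]
        masses = _masses_for_labels(labels, mass_map, default_mass)
        return Structure(positions=positions, masses=masses, labels=tuple(labels))
    if fmt == "xyz":
        _, labels, positions, _, masses = read_extxyz_frames(path)[0]
        if masses is None:
            masses = _masses_for_labels(labels, mass_map, default_mass)
        return Structure(positions=positions, masses=masses, labels=tuple(labels))
    raise ValueError(f"unsupported structure format: {fmt}")


def read_trajectory(
    path,
    fmt: str | None = None,
    mass_map: dict[str, float] | None = None,
    default_mass: float | None = DEFAULT_BEAD_MASS,
) -> Trajectory:
    """Read a GRO or extended-XYZ trajectory; velocities parsed when present."""
    fmt = _infer_format(path, fmt)
    if fmt == "gro":
        raw = [(t, lab, p, v, None) for t, lab, p, v in read_gro_frames(path)]
    elif fmt == "xyz":
        raw = read_extxyz_frames(path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")
    counts = {p.shape[0] for _, _, p, _, _ in raw}
    if len(counts) != 1:
        raise ValueError(f"inconsistent bead counts across frames: {sorted(counts)}")
    times = [t for t, *_ in raw]
    if any(t is None for t in times):
        raise ValueError("missing time metadata on one or more frames")
    labels = raw[0][1]
    masses = raw[0][4]
    if masses is None:
        masses = _masses_for_labels(labels, mass_map, default_mass)
    structure = Structure(
        positions=raw[0][2], masses=masses, labels=tuple(labels)
    )
    frames = tuple(
        Frame(time=t, positions=p, velocities=v) for t, _, p, v, _ in raw
    )
    times_arr = np.array(times)
    dt = None
    if len(times_arr) > 1:
        steps = np.diff(times_arr)
        if np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            dt = float(steps[0])
    return Trajectory(structure, frames, dt=dt)


def _read_pdb_structure(
    path,
    mass_map: dict[str, float] | None = None,
    default_mass: float | None = None,
) -> Structure:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    positions, masses, labels = [], [], []
    mass_map = mass_map or {}
    for atom in model.get_atoms():
        name = atom.get_name()
        element = (atom.element or "").upper()
        if name in mass_map:
            mass = mass_map[name]
        elif element in ELEMENT_MASSES:
            mass = ELEMENT_MASSES[element]
        elif default_mass is not None:
            mass = default_mass
        else:
            raise ValueError(
                f"unknown element for atom {name!r} and no mass override given"
            )
        positions.append(atom.coord / 10.0)  # Angstrom -> nm
        masses.append(mass)
        labels.append(name)
    if not positions:
        raise ValueError(f"no atoms found in {path}")
    return Structure(
        positions=np.asarray(positions),
        masses=np.asarray(masses),
        labels=tuple(labels),
    )


def backbone_bead_structure(pdb_path) -> Structure:
    """Map each residue to one bead at the COM of its backbone atoms (N, CA, C, O).

    Bead mass is the summed backbone atom mass.  Residues missing any of the
    four backbone atoms are skipped.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(pdb_path))[0]
    beads, masses, labels = [], [], []
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":
                continue
            atoms = [a for a in residue if a.get_name() in BACKBONE_ATOMS]
            if len(atoms) < len(BACKBONE_ATOMS):
                continue
            m = np.array([ELEMENT_MASSES[a.element.upper()] for a in atoms])
            x = np.array([a.coord for a in atoms]) / 10.0
            beads.append((m[:, None] * x).sum(axis=0) / m.sum())
            masses.append(m.sum())
            labels.append(residue.get_resname())
    if not beads:
        raise ValueError(f"no complete backbone residues in {pdb_path}")
    return Structure(
        positions=np.asarray(beads),
        masses=np.asarray(masses),
        labels=tuple(labels),
    )


def ubiquitin_backbone_structure() -> Structure:
    """Backbone-bead structure of the bundled ubiquitin crystal coordinates."""
    ref = importlib.resources.files("rotoshear") / "data" / "1ubq_backbone.pdb"
    with importlib.resources.as_file(ref) as path:
        return backbone_bead_structure(path)


def write_motionspec(motion: MotionSpec, path) -> None:
    Path(path).write_text(motion.to_json() + "\n")


def read_motionspec(path) -> MotionSpec:
    return MotionSpec.from_json(Path(path).read_text())
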