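"""Kinetic-energy decomposition in the laboratory and Eckart frames.

Laboratory frame (three terms):

    T = T_trans + T_rot_lab + T_vib_lab
      = 1/2 M |v_cm|^2 + 1/2 w.J.w + 1/2 sum m |v - v_cm - w x (r - r_cm)|^2

Eckart frame (five terms):

    T = T_trans + T_rot_eck + T_vib_nonang + T_vib_ang + T_cori
      = T_trans + 1/2 O.J.O + 1/2 sum m |v~|^2 + 1/2 sum m |u|^2 + O.J.O_v

Because the apparent angular velocity satisfies ``w = O + O_v`` exactly, both
decompositions close on the direct total ``1/2 sum m |v|^2`` to machine
precision, and the inter-frame relations

    T_vib_lab = T_vib_nonang            (eq. 19 analogue)
    T_rot_lab = T_rot_eck + T_vib_ang + T_cori   (eq. 20 analogue)

hold identically.  Energies are in kJ/mol (== amu nm^2 / ps^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Structure, Trajectory
from .eckart import (
    EckartState,
    LabRotationState,
    eckart_angular_velocity,
    lab_rotation_state,
)

__all__ = [
    "LabKinetic",
    "EckartKinetic",
    "KineticDecomposition",
    "FrameRelationReport",
    "EnergyTimeSeries",
    "kinetic_lab",
    "kinetic_eckart",
    "decompose_frame",
    "decompose_trajectory",
    "frame_relations",
    "timeseries_stats",
]

_CROSSCHECK_RTOL = 1e-8

LAB_COMPONENTS = ("T_trans", "T_rot_lab", "T_vib_lab")
ECKART_COMPONENTS = ("T_trans", "T_rot_eck", "T_vib_nonang", "T_vib_ang", "T_cori")


@dataclass(frozen=True)
class LabKinetic:
    frame_time: float
    T_total: float
    T_trans: float
    T_rot_lab: float
    T_vib_lab: float
    coriolis_lab: float  # eq. 14 cross term; identically ~0 in the lab frame


@dataclass(frozen=True)
class EckartKinetic:
    frame_time: float
    T_total: float
    T_trans: float
    T_rot_eck: float
    T_vib_nonang: float
    T_vib_ang: float
    T_cori: float


@dataclass(frozen=True)
class KineticDecomposition:
    """Lab triple and Eckart quintuple for a single frame."""

    frame_time: float
    T_total: float
    T_trans: float
    lab: LabKinetic
    eckart: EckartKinetic

    def lab_terms(self) -> dict[str, float]:
        return {
            "T_trans": self.T_trans,
            "T_rot_lab": self.lab.T_rot_lab,
            "T_vib_lab": self.lab.T_vib_lab,
        }

    def eckart_terms(self) -> dict[str, float]:
        return {
            "T_trans": self.T_trans,
            "T_rot_eck": self.eckart.T_rot_eck,
            "T_vib_nonang": self.eckart.T_vib_nonang,
            "T_vib_ang": self.eckart.T_vib_ang,
            "T_cori": self.eckart.T_cori,
        }


def _direct_total(frame: Frame, structure: Structure) -> float:
    vel = frame.require_velocities()
    return float(0.5 * (structure.masses * (vel * vel).sum(axis=1)).sum())


def kinetic_lab(
    frame: Frame, structure: Structure, lab_state: LabRotationState | None = None
) -> LabKinetic:
    """Three-term laboratory decomposition of the total kinetic energy.

    The vibrational term is computed both by residual subtraction and by the
    direct sum over residual velocities; a relative discrepancy above 1e-8
    raises a diagnostics warning (transcription-error tripwire).
    """
    if lab_state is None:
        lab_state = lab_rotation_state(frame, structure)
    m = structure.masses
    vel = frame.require_velocities()
    T_total = _direct_total(frame, structure)
    T_trans = float(0.5 * structure.total_mass * lab_state.com_velocity @ lab_state.com_velocity)
    omega = lab_state.omega
    T_rot = float(0.5 * omega @ lab_state.inertia @ omega)
    T_vib = T_total - T_trans - T_rot
    rel = frame.positions - lab_state.com
    resid = vel - lab_state.com_velocity - np.cross(omega, rel)
    T_vib_direct = float(0.5 * (m * (resid * resid).sum(axis=1)).sum())
    scale = max(abs(T_total), 1.0)
    if abs(T_vib - T_vib_direct) > _CROSSCHECK_RTOL * scale:
        warnings.warn(
            "lab vibrational energy cross-check failed: "
            f"residual={T_vib:.3e} direct={T_vib_direct:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
    coriolis_lab = float(omega @ (lab_state.angular_momentum - lab_state.inertia @ omega))
    return LabKinetic(
        frame_time=frame.time,
        T_total=T_total,
        T_trans=T_trans,
        T_rot_lab=T_rot,
        T_vib_lab=T_vib_direct,
        coriolis_lab=coriolis_lab,
    )


def kinetic_eckart(
    frame: Frame, structure: Structure, eckart_state: EckartState | None = None
) -> EckartKinetic:
    """Five-term Eckart-frame decomposition of the total kinetic energy."""
    if eckart_state is None:
        eckart_state = eckart_angular_velocity(frame, structure)
    m = structure.masses
    st = eckart_state
    T_total = _direct_total(frame, structure)
    T_trans = float(0.5 * structure.total_mass * st.com_velocity @ st.com_velocity)
    T_rot = float(0.5 * st.Omega @ st.inertia @ st.Omega)
    T_nonang = float(0.5 * (m * (st.v_nonang * st.v_nonang).sum(axis=1)).sum())
    T_ang = float(0.5 * (m * (st.v_ang * st.v_ang).sum(axis=1)).sum())
    rel = frame.positions - st.com
    T_cori = float(
        (m * (np.cross(st.Omega, rel) * st.delta_v).sum(axis=1)).sum()
    )
    return EckartKinetic(
        frame_time=frame.time,
        T_total=T_total,
        T_trans=T_trans,
        T_rot_eck=T_rot,
        T_vib_nonang=T_nonang,
        T_vib_ang=T_ang,
        T_cori=T_cori,
    )


def decompose_frame(
    frame: Frame,
    structure: Structure,
    reference: Structure | None = None,
) -> KineticDecomposition:
    """Both decompositions of one frame (reference defaults to ``structure``)."""
    reference = reference if reference is not None else structure
    lab = kinetic_lab(frame, structure)
    eck = kinetic_eckart(frame, structure, eckart_angular_velocity(frame, reference))
    return KineticDecomposition(
        frame_time=frame.time,
        T_total=lab.T_total,
        T_trans=lab.T_trans,
        lab=lab,
        eckart=eck,
    )


def decompose_trajectory(
    trajectory: Trajectory, reference: Structure | None = None
) -> list[KineticDecomposition]:
    return [
        decompose_frame(f, trajectory.structure, reference) for f in trajectory
    ]


@dataclass(frozen=True)
class FrameRelationReport:
    """Residuals of the inter-frame kinetic-energy relations."""

    vib_residual: float  # |T_vib_lab - T_vib_nonang|
    rot_residual: float  # |T_rot_lab - (T_rot_eck + T_vib_ang + T_cori)|
    total_residual: float  # |T_total(lab) - T_total(eckart)|
    T_total: float
    passed: bool


def frame_relations(
    lab: LabKinetic, eck: EckartKinetic, rtol: float = 1e-10
) -> FrameRelationReport:
    """Evaluate both sides of the lab/Eckart bridging relations."""
    vib_res = abs(lab.T_vib_lab - eck.T_vib_nonang)
    rot_res = abs(lab.T_rot_lab - (eck.T_rot_eck + eck.T_vib_ang + eck.T_cori))
    tot_res = abs(lab.T_total - eck.T_total)
    scale = max(abs(lab.T_total), np.finfo(float).tiny)
    passed = max(vib_res, rot_res, tot_res) < rtol * max(scale, 1.0)
    return FrameRelationReport(
        vib_residual=vib_res,
        rot_residual=rot_res,
        total_residual=tot_res,
        T_total=lab.T_total,
        passed=bool(passed),
    )


@dataclass(frozen=True)
class EnergyTimeSeries:
    """Per-component means, block standard errors, and fractions."""

    records: tuple[KineticDecomposition, ...]
    means: dict[str, float]
    standard_errors: dict[str, float]
    fractions_of_total: dict[str, float]
    fractions_of_internal: dict[str, float] = field(default_factory=dict)
    block_length: int = 1


def _block_se(values: np.ndarray, block_length: int) -> float:
    n_blocks = len(values) // block_length
    if n_blocks < 2:
        return float("nan")
    trimmed = values[: n_blocks * block_length].reshape(n_blocks, block_length)
    block_means = trimmed.mean(axis=1)
    return float(block_means.std(ddof=1) / np.sqrt(n_blocks))


def timeseries_stats(
    records: list[KineticDecomposition], block_length: int = 50
) -> EnergyTimeSeries:
    """Aggregate a decomposition series: means, block SEs, mean fractions.

    Fractions are averaged per frame; the lab triple and the Eckart quintuple
    (with signed Coriolis) each sum to 1 under the ``fractions_of_total``
    normalization.  ``fractions_of_internal`` excludes T_trans from the
    denominator (reported alongside because the reference normalization for
    relative contributions is ambiguous).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if block_length < 1 or block_length > len(records):
        raise ValueError("block_length must be in [1, len(records)]")
    series: dict[str, np.ndarray] = {
        "T_total": np.array([r.T_total for r in records]),
        "T_trans": np.array([r.T_trans for r in records]),
        "T_rot_lab": np.array([r.lab.T_rot_lab for r in records]),
        "T_vib_lab": np.array([r.lab.T_vib_lab for r in records]),
        "T_rot_eck": np.array([r.eckart.T_rot_eck for r in records]),
        "T_vib_nonang": np.array([r.eckart.T_vib_nonang for r in records]),
        "T_vib_ang": np.array([r.eckart.T_vib_ang for r in records]),
        "T_cori": np.array([r.eckart.T_cori for r in records]),
    }
    means = {k: float(v.mean()) for k, v in series.items()}
    ses = {k: _block_se(v, block_length) for k, v in series.items()}
    total = series["T_total"]
    internal = total - series["T_trans"]
    frac_tot: dict[str, float] = {}
    frac_int: dict[str, float] = {}
    for k, v in series.items():
        if k == "T_total":
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_tot[k] = float(np.mean(np.where(total != 0, v / total, np.nan)))
            if k != "T_trans":
                frac_int[k] = float(
                    np.mean(np.where(internal != 0, v / internal, np.nan))
                )
    return EnergyTimeSeries(
        records=tuple(records),
        means=means,
        standard_errors=ses,
        fractions_of_total=frac_tot,
        fractions_of_internal=frac_int,
        block_length=block_length,
    )
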