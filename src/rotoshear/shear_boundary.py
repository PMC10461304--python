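"""Open-boundary shear-flow formulas and DPD weight functions.

Pure functions only — no particle insertion and no integration of equations
of motion.  Geometry convention: ``n`` is the unit normal of the buffer/ROI
interface pointing into the region of interest, ``t`` the unit flow
direction, and the imposed profile is ``v1 = gamma_dot * x2``.  All
quantities use the amu/nm/ps system (pressure in kJ mol^-1 nm^-3).

The bulk viscosity ``zeta`` is carried for completeness (it enters the
isotropic stress ``pi = -zeta div v``) but none of the shear-flow momentum
flux components implemented here contain it, since the imposed linear shear
profile is divergence-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ShearBoundaryParams",
    "BufferState",
    "momentum_flux_tensor",
    "boundary_force",
    "distribute_buffer_force",
    "dpd_weights",
    "buffer_feedback",
]

WeightSpec = Callable[[np.ndarray], np.ndarray] | Sequence[float] | None


@dataclass(frozen=True)
class ShearBoundaryParams:
    """Parameters of the open-boundary shear setup."""

    gamma_dot: float  # shear rate, 1/ps
    p: float  # normal load (pressure), kJ mol^-1 nm^-3
    eta: float  # dynamic viscosity
    zeta: float = 0.0  # bulk viscosity (carried, unused by the shear components)
    rho: float = 0.0  # mass density
    n: tuple[float, float, float] = (0.0, 1.0, 0.0)  # buffer->ROI normal
    t: tuple[float, float, float] = (1.0, 0.0, 0.0)  # flow direction
    area: float = 1.0  # interface area, nm^2
    D: int = 3  # spatial dimension

    def __post_init__(self) -> None:
        n = np.asarray(self.n, float)
        t = np.asarray(self.t, float)
        if abs(np.linalg.norm(n) - 1) > 1e-10 or abs(np.linalg.norm(t) - 1) > 1e-10:
            raise ValueError("n and t must be unit vectors")
        if abs(n @ t) > 1e-10:
            raise ValueError("n and t must be orthogonal")
        if self.area <= 0:
            raise ValueError("area must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(self.n, float)

    @property
    def tangent(self) -> np.ndarray:
        return np.asarray(self.t, float)


@dataclass(frozen=True)
class BufferState:
    """Particle-count state of one buffer region."""

    N_B: int
    N_target: int
    dt: float  # time step, ps
    tau_B: float  # buffer relaxation time, ps

    def __post_init__(self) -> None:
        if self.N_B < 0 or self.N_target < 0:
            raise ValueError("particle counts must be >= 0")
        if self.tau_B <= 0 or self.dt <= 0:
            raise ValueError("tau_B and dt must be positive")


def momentum_flux_tensor(params: ShearBoundaryParams, x2: float) -> np.ndarray:
    """Momentum flux tensor of the imposed linear shear profile at height x2.

    J11 = rho gdot^2 x2^2 + p, J12 = J21 = -eta gdot, J22 = J33 = p, all the
    remaining off-diagonal components vanish.  For gdot = 0 this reduces to
    the constant-load form p*I.
    """
    g = params.gamma_dot
    J = np.zeros((3, 3))
    J[0, 0] = params.rho * g * g * x2 * x2 + params.p
    J[0, 1] = J[1, 0] = -params.eta * g
    J[1, 1] = params.p
    J[2, 2] = params.p
    return J


def boundary_force(
    params: ShearBoundaryParams,
    flux: np.ndarray,
    exchanged_momentum: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    dt: float = 1.0,
) -> np.ndarray:
    """Total external buffer force from the interface momentum balance.

    ``F_ext = A [(n.J.n) n + (t.J.n) t] - sum_i' Delta(m v)/dt`` where the
    exchanged momentum carries + for insertions and - for deletions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    flux = np.asarray(flux, float)
    n, t = params.normal, params.tangent
    flux_part = params.area * ((n @ flux @ n) * n + (t @ flux @ n) * t)
    return flux_part - np.asarray(exchanged_momentum, float) / dt


def _resolve_weights(spec: WeightSpec, positions: np.ndarray) -> np.ndarray:
    n = positions.shape[0]
    if spec is None:
        w = np.full(n, 1.0)
    elif callable(spec):
        w = np.asarray(spec(positions), float)
        if w.shape != (n,):
            raise ValueError("weight callable must return one weight per particle")
    else:
        w = np.asarray(spec, float)
        if w.shape != (n,):
            raise ValueError("weight sequence length must match particle count")
    total = w.sum()
    if total == 0:
        raise ZeroDivisionError("weights sum to zero")
    return w / total


def distribute_buffer_force(
    F_ext: np.ndarray,
    params: ShearBoundaryParams,
    buffer_positions: np.ndarray,
    g_parallel: WeightSpec = None,
    g_perp: WeightSpec = None,
) -> np.ndarray:
    """Split the external force over buffer particles with normalized weights.

    Per particle: ``f_i = g||_i (F.n) n + g+_i (F.t) t`` with each weight set
    normalized to sum to one, so the per-particle forces sum to ``F_ext``
    exactly.  Any force component outside span(n, t) is distributed
    uniformly to preserve the exact-sum contract.
    """
    positions = np.atleast_2d(np.asarray(buffer_positions, float))
    if positions.shape[0] < 1:
        raise ValueError("need at least one buffer particle")
    F_ext = np.asarray(F_ext, float)
    n, t = params.normal, params.tangent
    F_par = F_ext @ n
    F_perp = F_ext @ t
    F_rest = F_ext - F_par * n - F_perp * t
    w_par = _resolve_weights(g_parallel, positions)
    w_perp = _resolve_weights(g_perp, positions)
    forces = (
        np.outer(w_par, F_par * n)
        + np.outer(w_perp, F_perp * t)
        + F_rest / positions.shape[0]
    )
    return forces


def dpd_weights(r, r_c: float):
    """DPD dissipative/random weight pair ``(w_D, w_R)`` at separation r.

    ``w_R(r) = 1 - r/r_c`` for r < r_c (zero beyond the cutoff) and
    ``w_D = (w_R)^2``, the fluctuation-dissipation constraint.  Accepts
    scalars or arrays.
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    r_arr = np.asarray(r, float)
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    w_r = np.clip(1.0 - r_arr / r_c, 0.0, None)
    w_d = w_r * w_r
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(w_d), float(w_r)
    return w_d, w_r


def buffer_feedback(state: BufferState) -> float:
    """Feedback increment ``Delta N_B = (dt/tau_B)(<N_B> - N_B)``."""
    return (state.dt / state.tau_B) * (state.N_target - state.N_B)
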