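"""Flat TOML run configuration.

Defaults mirror the simulation culture the package targets: 0.02 ps sampling
step, elastic-network window 0.5-0.9 nm with k = 550 kJ/mol/nm^2 and break
multiplier 1.35.  CLI flags mirror config keys and take precedence.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from ..core import DEFAULT_BEAD_MASS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    trajectory: str | None = None
    reference: str | None = None
    fmt: str | None = None
    frame_start: int = 0
    frame_stop: int | None = None
    stride: int = 1
    default_mass: float = DEFAULT_BEAD_MASS
    dt: float = 0.02  # ps
    seed: int = 0
    outdir: str = "rotoshear_out"
    block_length: int = 50
    rereference_stride: int = 0  # 0 = fixed reference
    orthogonality_tol: float = 1e-10
    eckart_residual_tol: float = 1e-9
    en_lower: float = 0.5  # nm
    en_upper: float = 0.9  # nm
    en_k: float = 550.0  # kJ/mol/nm^2
    en_break_multiplier: float = 1.35
    boundary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        for key in ("trajectory", "reference"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key} file not found: {path}")


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
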