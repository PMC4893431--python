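"""Shared field containers for one time frame on a structured grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_ops import StructuredGrid

__all__ = ["VelocityField", "DopplerField", "PressureField"]


@dataclass
class VelocityField:
    """Three velocity components (m/s) on the full grid, one time frame.

    ``v`` has shape ``(3, nx, ny, nz)``; components are meaningful inside
    the frame's mask, values outside are extrapolated/zero padding.
    """

    grid: StructuredGrid
    v: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (3, *self.grid.shape):
            raise ValueError(
                f"velocity shape {self.v.shape} != (3, {self.grid.shape})"
            )

    @property
    def v1(self) -> np.ndarray:
        return self.v[0]

    @property
    def v2(self) -> np.ndarray:
        return self.v[1]

    @property
    def v3(self) -> np.ndarray:
        return self.v[2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.v**2).sum(axis=0))


@dataclass
class DopplerField:
    """Beam-projected scalar velocity 𝒟 = a·v (m/s) for one frame."""

    grid: StructuredGrid
    values: np.ndarray
    beam: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    frame_time: float = 0.0
    frame_dt: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("Doppler values shape does not match grid")
        self.beam = np.asarray(self.beam, dtype=float)
        if abs(np.linalg.norm(self.beam) - 1.0) > 1e-8:
            raise ValueError("beam direction must be a unit vector")


@dataclass
class PressureField:
    """Pressure (Pa) on the grid, gauge-fixed to zero mean over the mask."""

    grid: StructuredGrid
    p: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.grid.shape:
            raise ValueError("pressure shape does not match grid")
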