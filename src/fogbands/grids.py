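"""Rectangular scalar fields shared by the simulators and the image pipeline.

Array convention
----------------
``values[i, j]`` is the sample at ``(x = i*dx, y = j*dy)``: axis 0 is the
fog/advection direction *x*, axis 1 the transverse direction *y*.  Angles are
measured in degrees counter-clockwise from the +x axis ("east").  Rasters are
transposed on PNG/TIFF export so that *x* runs along image columns and *y*
upward.

Boundary conditions are carried as tags on the field: the models use
Dirichlet walls in *x* (biomass pinned to zero at the upwind and downwind
edges, i.e. the first and last rows of ``values``) and periodic wrap in *y*.
For a Dirichlet axis the grid includes both wall nodes, so the box size is
``(n - 1) * spacing``; for a periodic axis it is ``n * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_BC = ("dirichlet", "periodic")


@dataclass
class Field2D:
    """A scalar field b(x, y) on a rectangular grid with BC tags."""

    values: np.ndarray
    dx: float = 1.0
    dy: float = 1.0
    bc_x: str = "dirichlet"
    bc_y: str = "periodic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"Field2D requires a 2-D array, got shape {self.values.shape}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")
        if self.bc_x not in _BC or self.bc_y not in _BC:
            raise ValueError(f"boundary tags must be one of {_BC}")

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def Lx(self) -> float:
        return (self.nx - 1) * self.dx if self.bc_x == "dirichlet" else self.nx * self.dx

    @property
    def Ly(self) -> float:
        return (self.ny - 1) * self.dy if self.bc_y == "dirichlet" else self.ny * self.dy

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        return np.arange(self.ny) * self.dy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")

    def copy(self) -> "Field2D":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray) -> "Field2D":
        return replace(self, values=np.asarray(values, dtype=float))


def fold_180(angle_deg):
    """Reduce an orientation (axial angle) to [0, 180)."""
    return np.mod(angle_deg, 180.0)


def fold_pm90(angle_deg):
    """Fold an angular difference between orientations to [-90, 90)."""
    return np.mod(np.asarray(angle_deg, dtype=float) + 90.0, 180.0) - 90.0
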