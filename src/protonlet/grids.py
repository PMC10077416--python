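"""Voxel-grid and structure-mask containers shared by the whole package.

Axis convention: arrays are indexed ``(ix, iy, iz)`` with x = patient left,
y = posterior (anterior surfaces sit at negative y) and z = superior.  All
geometric quantities are in millimetres; volumes are reported in cc.

Voxels excluded from LET / variable-RBE statistics (e.g. below the dose
threshold) carry :data:`SENTINEL` (NaN) in LET-like grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel stored in voxels excluded from the evaluable volume.
SENTINEL: float = float("nan")

_QUANTITIES = ("dose_Gy", "let_keVum", "rbe", "dose_Gy_rbe", "delta_Gy_rbe", "mask")


class GeometryError(ValueError):
    """Raised when grids or masks with incompatible geometry are combined."""


@dataclass
class VoxelGrid:
    """A 3-D scalar field (dose, LET, RBE or Δdose) on a regular grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; coerced to float64.
    spacing
        Voxel spacing per axis in mm.
    origin
        Position of the corner of voxel ``(0, 0, 0)`` in mm; voxel centres
        are at ``origin + (index + 0.5) * spacing``.
    quantity
        What the field holds, one of ``dose_Gy``, ``let_keVum``, ``rbe``,
        ``dose_Gy_rbe``, ``delta_Gy_rbe`` or ``mask``.
    provenance
        Free-text note on how the grid was produced (kept through I/O).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: str = "dose_Gy"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"grid must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}; expected one of {_QUANTITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (spacing product / 1000)."""
        return math.prod(self.spacing) / 1000.0

    def congruent_with(self, other: "VoxelGrid | StructureMask", atol: float = 1e-6) -> bool:
        o_shape = other.shape if isinstance(other, VoxelGrid) else other.mask.shape
        o_spacing = other.spacing
        return self.shape == tuple(o_shape) and all(
            abs(a - b) <= atol for a, b in zip(self.spacing, o_spacing)
        )

    def like(self, values: np.ndarray, quantity: str | None = None,
             provenance: str | None = None) -> "VoxelGrid":
        """A new grid with the same geometry but different values."""
        return VoxelGrid(
            np.asarray(values, dtype=np.float64),
            self.spacing,
            self.origin,
            quantity if quantity is not None else self.quantity,
            provenance if provenance is not None else self.provenance,
        )

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D arrays of voxel-centre coordinates per axis, in mm."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class StructureMask:
    """Boolean voxel mask naming an anatomical structure."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return math.prod(self.spacing) / 1000.0

    @property
    def volume_cc(self) -> float:
        """Structure volume = voxel count × voxel volume, exactly."""
        return int(self.mask.sum()) * self.voxel_volume_cc

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def require_congruent(first: VoxelGrid, *others: "VoxelGrid | StructureMask") -> None:
    """Raise :class:`GeometryError` unless all grids/masks share geometry."""
    for other in others:
        if not first.congruent_with(other):
            name = getattr(other, "name", getattr(other, "quantity", "grid"))
            raise GeometryError(
                f"geometry mismatch: {first.shape}@{first.spacing} vs "
                f"{other.shape if isinstance(other, VoxelGrid) else other.mask.shape}"
                f"@{other.spacing} ({name})"
            )
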