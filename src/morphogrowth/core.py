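"""Core in-memory containers for volumetric data.

Conventions used throughout the package:

* Arrays are indexed ``[i, j, k]`` along the (x, y, z) axes of a
  right-handed coordinate frame.
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)``
  is ``origin + index * spacing`` (mm).
* Displacement fields are stored in millimetres, not voxels, and define
  the mapping ``x -> x + u(x)`` on physical coordinates.  All morphometry
  is therefore done in physical space and anisotropic voxels are handled
  correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .errors import GridError

__all__ = [
    "VolumeGrid",
    "LabelVolume",
    "DisplacementField",
    "GrowthSeries",
    "check_same_grid",
]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise GridError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridError(f"volume must be 3-D, got ndim={self.values.ndim}")
        if any(s < 2 for s in self.values.shape):
            raise GridError(f"volume must be >= 2 voxels per axis, got {self.values.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise GridError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("volume values must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical_coordinates(self) -> np.ndarray:
        """Return an ``(nx, ny, nz, 3)`` array of voxel centre positions in mm."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def same_grid_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )


@dataclass
class LabelVolume:
    """Integer segmentation on the same lattice as a companion :class:`VolumeGrid`.

    ``label_dict`` maps region names to integer ids; background is 0 and is
    not listed.
    """

    labels: np.ndarray
    label_dict: Dict[str, int]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GridError(f"label volume must be 3-D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GridError(f"labels must be integer-typed, got {self.labels.dtype}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        ids = set(np.unique(self.labels).tolist()) - {0}
        known = set(self.label_dict.values())
        if not ids <= known:
            raise GridError(f"label ids {sorted(ids - known)} not in label_dict")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self) -> np.ndarray:
        """Boolean object mask: every non-background voxel."""
        return self.labels > 0

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_dict[name]

    def same_grid_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector u(x) in mm defining the map ``x -> x + u(x)``.

    Component order matches the array axis order (x, y, z).
    """

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise GridError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(np.isfinite(self.vectors)):
            raise GridError("displacement vectors must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def same_grid_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )


@dataclass
class GrowthSeries:
    """An ordered weekly series of volumes + segmentations and, when the
    series comes from the phantom generator, the ground-truth displacement
    field for each consecutive pair (week k -> week k+1)."""

    volumes: List[VolumeGrid]
    labels: List[LabelVolume]
    true_fields: List[DisplacementField] | None = None

    def __post_init__(self):
        if len(self.volumes) != len(self.labels):
            raise GridError("series needs one label volume per intensity volume")
        if len(self.volumes) < 2:
            raise GridError("series needs at least 2 timepoints")
        if self.true_fields is not None and len(self.true_fields) != len(self.volumes) - 1:
            raise GridError("series needs one ground-truth field per consecutive pair")

    @property
    def n_weeks(self) -> int:
        return len(self.volumes)


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise :class:`GridError` unless the two objects share shape/spacing/origin."""
    if not a.same_grid_as(b):
        raise GridError(
            f"{what} are on different grids: "
            f"{a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
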