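"""Regular-grid volume and ROI-mask containers.

All volumes live on an axis-aligned regular 3D grid in physical mm
coordinates. Arrays are indexed ``values[ix, iy, iz]``; the physical
position of voxel ``(i, j, k)`` is ``origin_mm + (i, j, k) * spacing_mm``
(voxel-center convention, 0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeGrid:
    """Scalar field (activity counts or HU) on a regular 3D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing_mm : array-like of 3 floats
        Per-axis voxel size in mm; strictly positive.
    origin_mm : array-like of 3 floats
        Physical position of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("spacing_mm must be strictly positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of physical points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        return (pts - self.origin_mm) / self.spacing_mm

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return self.origin_mm + idx * self.spacing_mm

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center physical coordinates."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid | ROIMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def copy_with(self, values: np.ndarray) -> "VolumeGrid":
        """New volume with the same geometry and the given values."""
        return VolumeGrid(np.asarray(values), self.spacing_mm.copy(), self.origin_mm.copy())


@dataclass
class ROIMask:
    """Boolean mask geometrically aligned with a :class:`VolumeGrid`."""

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("mask must be a non-empty 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("spacing_mm must be strictly positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the true voxels."""
        if self.count == 0:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.values).mean(axis=0)
        return self.origin_mm + idx * self.spacing_mm

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        return (pts - self.origin_mm) / self.spacing_mm

    def copy_with(self, values: np.ndarray) -> "ROIMask":
        return ROIMask(np.asarray(values), self.spacing_mm.copy(), self.origin_mm.copy())
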