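"""Beam geometry and the beam's-eye-view (BEV) sampling lattice.

The BEV is the 2D plane perpendicular to the beam direction. Sampling
lines run parallel to the beam through anchors on a regular (u, v)
lattice in that plane; per-line depth profiles and range differences
are indexed by those anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BeamGeometry:
    """Parallel-beam geometry: unit travel direction, orthonormal in-plane
    BEV basis (u, v) and the isocenter.

    The triplet {u_axis, v_axis, direction} is right-handed
    (u x v = direction). A BEV anchor (a, b) maps to the physical point
    ``isocenter + a*u_axis + b*v_axis``.
    """

    direction: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    isocenter_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3)
        self.u_axis = np.asarray(self.u_axis, dtype=np.float64).reshape(3)
        self.v_axis = np.asarray(self.v_axis, dtype=np.float64).reshape(3)
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=np.float64).reshape(3)
        for name, vec in (("direction", self.direction), ("u_axis", self.u_axis),
                          ("v_axis", self.v_axis)):
            if not np.isclose(np.linalg.norm(vec), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be a unit vector")
        gram = np.array([
            [self.u_axis @ self.v_axis, self.u_axis @ self.direction],
            [0.0, self.v_axis @ self.direction],
        ])
        if not np.allclose(gram, 0.0, atol=1e-8):
            raise ValueError("{u_axis, v_axis, direction} must be orthonormal")
        if not np.allclose(np.cross(self.u_axis, self.v_axis), self.direction, atol=1e-8):
            raise ValueError("{u_axis, v_axis, direction} must be right-handed")

    @classmethod
    def from_direction(cls, direction, isocenter_mm=(0.0, 0.0, 0.0),
                       superior=(0.0, 0.0, 1.0)) -> "BeamGeometry":
        """Build an orthonormal BEV basis from a beam direction alone.

        u = normalize(direction x superior), v = direction x u. When the
        beam is (anti)parallel to the superior axis the patient-anterior
        (+y) axis is used instead.
        """
        d = np.asarray(direction, dtype=np.float64).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        d = d / n
        ref = np.asarray(superior, dtype=np.float64)
        u = np.cross(d, ref)
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(d, np.array([0.0, 1.0, 0.0]))
        u = u / np.linalg.norm(u)
        v = np.cross(d, u)
        return cls(d, u, v, np.asarray(isocenter_mm, dtype=np.float64))

    def anchors_to_world(self, anchors_uv: np.ndarray) -> np.ndarray:
        """Map (N, 2) BEV anchors to (N, 3) physical points on the BEV plane."""
        uv = np.atleast_2d(np.asarray(anchors_uv, dtype=np.float64))
        return (self.isocenter_mm
                + uv[:, 0:1] * self.u_axis
                + uv[:, 1:2] * self.v_axis)

    def world_to_bev(self, points_mm: np.ndarray) -> np.ndarray:
        """(u, v, s) coordinates of physical points: in-plane offsets and the
        along-beam coordinate s, all relative to the isocenter."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64)) - self.isocenter_mm
        return np.stack([pts @ self.u_axis, pts @ self.v_axis, pts @ self.direction],
                        axis=-1)


@dataclass
class SamplingGrid:
    """Regular lattice of BEV line anchors.

    Anchors per axis are ``min + k*spacing`` for
    ``k = 0 .. ceil((max-min)/spacing) - 1`` — a half-open interval
    [min, max) — and the grid is their Cartesian product.
    """

    extent_mm: tuple[tuple[float, float], tuple[float, float]]
    spacing_mm: float
    u_anchors: np.ndarray = field(init=False)
    v_anchors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        axes = []
        for lo, hi in self.extent_mm:
            if hi <= lo:
                raise ValueError("extent max must exceed min")
            n = int(np.ceil((hi - lo) / self.spacing_mm))
            axes.append(lo + self.spacing_mm * np.arange(n))
        self.u_anchors, self.v_anchors = axes

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.u_anchors), len(self.v_anchors)

    @property
    def n_lines(self) -> int:
        return len(self.u_anchors) * len(self.v_anchors)

    @property
    def positions(self) -> np.ndarray:
        """All (u, v) anchors, shape (n_lines, 2), u-major order."""
        uu, vv = np.meshgrid(self.u_anchors, self.v_anchors, indexing="ij")
        return np.stack([uu.ravel(), vv.ravel()], axis=1)


def make_sampling_grid(extent_mm, spacing_mm: float) -> SamplingGrid:
    """Construct the BEV sampling lattice.

    Parameters
    ----------
    extent_mm : (min, max) pair, or a pair of such pairs
        BEV extent per axis in mm. A single (min, max) applies to both
        axes. The lattice is half-open: [min, max).
    spacing_mm : float
        Line pitch in mm (the clinical default is 3 mm, the voxel size
        of the PET grid).
    """
    ext = np.asarray(extent_mm, dtype=np.float64)
    if ext.shape == (2,):
        extent = ((ext[0], ext[1]), (ext[0], ext[1]))
    elif ext.shape == (2, 2):
        extent = ((ext[0, 0], ext[0, 1]), (ext[1, 0], ext[1, 1]))
    else:
        raise ValueError("extent_mm must be (min, max) or ((umin, umax), (vmin, vmax))")
    return SamplingGrid(extent, float(spacing_mm))
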