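"""Sampling-line tracing in the beam's-eye view.

Every quantity here is indexed by a BEV anchor (u, v): the beam-parallel
line through that anchor is scanned against the body mask to find the
skin entry (depth 0) and exit, and activity volumes are sampled along it
by trilinear interpolation to build depth profiles.

Skin entry (depth 0) is the first voxel-center along the beam whose
body-mask value is true: the membership crossing is located by a coarse
scan plus bisection, and the entry is the projection of that first
in-body voxel's center onto the line direction. Measuring clip depth
"from the skin" and all profile depths share this convention; it cancels
in any R50 difference between co-registered volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import BeamGeometry, SamplingGrid
from .grids import ROIMask, VolumeGrid


@dataclass
class DepthProfile:
    """Activity sampled along one beam-parallel line.

    depths_mm are uniform, strictly increasing, with 0 at skin entry.
    ``valid`` is False when the line missed the body (a flag, not an
    exception, so full-grid sweeps can proceed).
    """

    depths_mm: np.ndarray
    values: np.ndarray
    line_anchor: tuple[float, float]
    valid: bool = True

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.valid:
            if self.depths_mm.size < 2 or np.any(np.diff(self.depths_mm) <= 0):
                raise ValueError("depths must be strictly increasing")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("profile values must be finite")


def _mask_lookup(mask: ROIMask, points_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel membership of physical points in a boolean mask."""
    idx = np.rint(mask.world_to_index(points_mm)).astype(np.int64)
    shape = np.asarray(mask.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=-1)
    out = np.zeros(points_mm.shape[:-1], dtype=bool)
    if np.any(inb):
        ii = idx[inb]
        out[inb] = mask.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def _beam_s_range(mask: ROIMask, geom: BeamGeometry) -> tuple[float, float]:
    """Along-beam coordinate range covered by the volume bounding box."""
    lo = mask.origin_mm - 0.5 * mask.spacing_mm
    hi = mask.origin_mm + (np.asarray(mask.shape) - 0.5) * mask.spacing_mm
    corners = np.array(
        [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]
    )
    s = (corners - geom.isocenter_mm) @ geom.direction
    return float(s.min()), float(s.max())


def trace_lines(
    anchors_uv: np.ndarray,
    geom: BeamGeometry,
    body_mask: ROIMask,
    scan_step_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate skin entry and body exit for beam-parallel lines.

    Returns ``(s_entry, s_exit, hit)``: along-beam coordinates (relative
    to the isocenter plane) of the first body crossing and the last body
    sample per line, and a boolean flag for lines that intersect the
    body at all. The first crossing is refined by bisection of the
    nearest-voxel membership function.
    """
    anchors_uv = np.atleast_2d(np.asarray(anchors_uv, dtype=np.float64))
    if scan_step_mm is None:
        scan_step_mm = 0.5 * float(body_mask.spacing_mm.min())
    s_lo, s_hi = _beam_s_range(body_mask, geom)
    ts = np.arange(s_lo - scan_step_mm, s_hi + 2 * scan_step_mm, scan_step_mm)
    base = geom.anchors_to_world(anchors_uv)  # (N, 3)
    pts = base[:, None, :] + ts[None, :, None] * geom.direction  # (N, M, 3)
    inside = _mask_lookup(body_mask, pts)  # (N, M)

    hit = inside.any(axis=1)
    first = np.argmax(inside, axis=1)
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    s_exit = ts[last].copy()

    # bisection-refine the membership crossing within (first-1, first];
    # hi_t converges to a point inside the first in-body voxel
    lo_t = ts[np.maximum(first - 1, 0)].copy()
    hi_t = ts[first].copy()
    for _ in range(20):
        mid = 0.5 * (lo_t + hi_t)
        mid_pts = base + mid[:, None] * geom.direction
        mid_in = _mask_lookup(body_mask, mid_pts)
        hi_t = np.where(mid_in, mid, hi_t)
        lo_t = np.where(mid_in, lo_t, mid)

    # depth 0 is the first voxel-center along the beam whose body value
    # is true: project that voxel's center onto the line direction
    in_pts = base + hi_t[:, None] * geom.direction
    vox = np.rint(body_mask.world_to_index(in_pts))
    centers = body_mask.origin_mm + vox * body_mask.spacing_mm
    s_entry = np.einsum("ij,j->i", centers - base, geom.direction)
    return s_entry, s_exit, hit


def sample_along_lines(
    volume: VolumeGrid,
    geom: BeamGeometry,
    anchors_uv: np.ndarray,
    s_start: np.ndarray,
    n_samples: int,
    step_mm: float,
) -> np.ndarray:
    """Trilinear samples of ``volume`` along beam-parallel lines.

    Returns an (N, n_samples) array; sample k of line i lies at
    ``anchor_i + (s_start_i + k*step_mm) * direction``. Out-of-support
    samples are zero.
    """
    anchors_uv = np.atleast_2d(np.asarray(anchors_uv, dtype=np.float64))
    base = geom.anchors_to_world(anchors_uv)
    ks = np.arange(n_samples) * step_mm
    pts = (base[:, None, :]
           + (s_start[:, None] + ks[None, :])[:, :, None] * geom.direction)
    idx = volume.world_to_index(pts.reshape(-1, 3))
    vals = map_coordinates(volume.values, idx.T, order=1, mode="constant", cval=0.0)
    return vals.reshape(anchors_uv.shape[0], n_samples)


def extract_profile(
    volume: VolumeGrid,
    body_mask: ROIMask,
    geom: BeamGeometry,
    anchor: tuple[float, float],
    step_mm: float = 1.0,
) -> DepthProfile:
    """Depth profile of ``volume`` along the beam-parallel line through a
    BEV anchor, sampled every ``step_mm`` from skin entry until the line
    exits the body (plus one step).

    A line that misses the body yields an invalid profile rather than an
    exception so that full-grid sweeps proceed.
    """
    uv = np.asarray(anchor, dtype=np.float64).reshape(1, 2)
    s_entry, s_exit, hit = trace_lines(uv, geom, body_mask)
    if not hit[0]:
        return DepthProfile(np.zeros(0), np.zeros(0), tuple(uv[0]), valid=False)
    n = int(np.ceil((s_exit[0] - s_entry[0]) / step_mm)) + 2
    values = sample_along_lines(volume, geom, uv, s_entry, n, step_mm)[0]
    depths = np.arange(n) * step_mm
    return DepthProfile(depths, values, (float(uv[0, 0]), float(uv[0, 1])), valid=True)


def project_mask_to_bev(
    mask: ROIMask,
    geom: BeamGeometry,
    grid: SamplingGrid,
    step_mm: float | None = None,
) -> np.ndarray:
    """Project an ROI mask onto the BEV sampling lattice.

    A BEV cell is true iff the beam-parallel line through its anchor
    intersects at least one true voxel (nearest-voxel lookup along the
    line at ``step_mm``, default half the smallest voxel dimension).
    Returns a boolean array of shape ``grid.shape``.
    """
    if mask.count == 0:
        return np.zeros(grid.shape, dtype=bool)
    if step_mm is None:
        step_mm = 0.5 * float(mask.spacing_mm.min())
    anchors = grid.positions
    s_lo, s_hi = _beam_s_range(mask, geom)
    ts = np.arange(s_lo - step_mm, s_hi + 2 * step_mm, step_mm)
    base = geom.anchors_to_world(anchors)
    pts = base[:, None, :] + ts[None, :, None] * geom.direction
    inside = _mask_lookup(mask, pts)
    return inside.any(axis=1).reshape(grid.shape)


def clip_skin_depth(
    clip_centroid_mm,
    geom: BeamGeometry,
    body_mask: ROIMask,
    scan_step_mm: float | None = None,
) -> float:
    """Along-beam distance from skin entry to a clip centroid.

    The beam-parallel line through the centroid is traced against the
    body mask; the depth is the centroid's along-beam coordinate minus
    the line's skin-entry coordinate.
    """
    c = np.asarray(clip_centroid_mm, dtype=np.float64).reshape(3)
    if not _mask_lookup(body_mask, c.reshape(1, 3))[0]:
        raise ValueError("clip centroid lies outside the body mask")
    uvs = geom.world_to_bev(c.reshape(1, 3))[0]
    s_entry, _, hit = trace_lines(uvs[:2].reshape(1, 2), geom, body_mask,
                                  scan_step_mm=scan_step_mm)
    if not hit[0]:
        raise ValueError("line through clip centroid misses the body")
    return float(uvs[2] - s_entry[0])
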