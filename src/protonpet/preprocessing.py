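"""Image preprocessing for PET range verification.

Covers the steps applied to the measured PET image before R50 analysis:
sliding-window mean smoothing (3x3 or 5x5, stride 1, zero padding),
target-area activity normalization against the predicted image, the
HU-override correction for Ti clips and their artifact shells on the
planning CT, and application of a rigid translation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import ROIMask, VolumeGrid

TI_HU_DEFAULT = 3000.0
ADIPOSE_HU_DEFAULT = -100.0


def smooth(volume: VolumeGrid, window: int = 3, mode: str = "slicewise2d") -> VolumeGrid:
    """Sliding-window mean with zero padding.

    Each output voxel is the arithmetic mean of the ``window``-wide
    neighborhood centered on it, with out-of-bounds neighbors counted
    as zero — the divisor is always the full window size, so edge
    voxels are attenuated. ``slicewise2d`` (default) smooths each axial
    (constant-z) slice with a 2D window; ``full3d`` uses a cubic window.
    Grid geometry is unchanged. The smoothing operator is linear.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive size (3 or 5)")
    if window not in (3, 5):
        raise ValueError("window must be 3 or 5")
    if mode not in ("slicewise2d", "full3d"):
        raise ValueError("mode must be 'slicewise2d' or 'full3d'")
    r = window // 2
    vals = volume.values
    if mode == "slicewise2d":
        pad = np.pad(vals, ((r, r), (r, r), (0, 0)))
        offsets = [(di, dj, 0) for di in range(window) for dj in range(window)]
        divisor = float(window * window)
    else:
        pad = np.pad(vals, r)
        offsets = [(di, dj, dk) for di in range(window)
                   for dj in range(window) for dk in range(window)]
        divisor = float(window**3)
    nx, ny, nz = vals.shape
    total = np.zeros_like(vals)
    # accumulate shifted copies in row-major window order so the result
    # is bit-identical to a per-voxel loop summing in the same order
    for (di, dj, dk) in offsets:
        total += pad[di:di + nx, dj:dj + ny, dk:dk + nz]
    return volume.copy_with(total / divisor)


def normalize_measured(
    measured: VolumeGrid, predicted: VolumeGrid, target: ROIMask
) -> tuple[VolumeGrid, float]:
    """Scale the measured image so its mean activity over the target
    area matches the predicted image's.

    factor = mean(predicted | target) / mean(measured | target); the
    returned volume is measured * factor. Activity magnitude is
    deliberately discarded by this step — only relative levels matter
    downstream, and the half-maximum analysis is itself scale-invariant.
    """
    if target.count == 0:
        raise ValueError("normalization target area is empty")
    sel = target.values
    m_mean = float(measured.values[sel].mean())
    p_mean = float(predicted.values[sel].mean())
    if m_mean <= 0:
        raise ValueError("measured activity mean over the target area is not positive")
    factor = p_mean / m_mean
    return measured.copy_with(measured.values * factor), factor


def apply_hu_override(
    ct: VolumeGrid,
    clip_mask: ROIMask,
    artifact_mask: ROIMask,
    ti_hu: float = TI_HU_DEFAULT,
    adipose_hu: float = ADIPOSE_HU_DEFAULT,
) -> VolumeGrid:
    """Tissue correction around Ti clips on the planning CT.

    Clip voxels are set to ``ti_hu`` (must exceed 1500, the threshold
    identifying Ti) and the surrounding artifact-shell voxels are
    reclassified to ``adipose_hu``, overwriting streaks. The masks must
    be disjoint; all other voxels are unchanged. Idempotent.
    """
    if ti_hu <= 1500:
        raise ValueError("ti_hu must exceed 1500 (Ti contouring threshold)")
    if np.any(clip_mask.values & artifact_mask.values):
        raise ValueError("clip and artifact masks overlap")
    out = ct.values.copy()
    out[clip_mask.values] = ti_hu
    out[artifact_mask.values] = adipose_hu
    return ct.copy_with(out)


def apply_rigid_translation(volume: VolumeGrid, t_mm) -> VolumeGrid:
    """Translate a volume's content by ``t_mm`` (physical mm).

    The output is sampled by trilinear interpolation at the input
    positions shifted by -t_mm; samples outside the input support are
    zero. A translation by an exact voxel pitch reduces to an integer
    roll with zero fill.
    """
    t = np.asarray(t_mm, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(t)):
        raise ValueError("translation must be finite")
    shift_vox = t / volume.spacing_mm
    out = ndimage.shift(volume.values, shift=shift_vox, order=1,
                        mode="constant", cval=0.0, prefilter=False)
    return volume.copy_with(out)
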