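"""Shared fixtures: slab phantoms, beam geometry and mask builders.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import protonpet as pp


@pytest.fixture(scope="session")
def beam_z() -> pp.BeamGeometry:
    """Beam travelling along +z with the BEV basis (u, v) = (-x, -y)."""
    return pp.BeamGeometry.from_direction((0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def slab_phantom():
    """Slab body entered at z = 0 with three non-overlapping Ti clips at
    skin depths 15, 24 and 30 mm."""
    # z count is odd so voxel centers land on z = 0: the slab's first
    # in-body voxel center (the depth origin) sits exactly at the surface
    spec = pp.PhantomSpec(
        grid_shape=(60, 60, 49),
        spacing_mm=(3.0, 3.0, 3.0),
        body=pp.SlabBody(axis=2, lo_mm=0.0, hi_mm=150.0),
        clip_list=[
            pp.Clip((-21.0, 0.0, 15.0), radius_mm=4.0),
            pp.Clip((21.0, 0.0, 30.0), radius_mm=4.0),
            pp.Clip((0.0, 21.0, 24.0), radius_mm=4.0),
        ],
        artifact_radius_mm=8.0,
        streak_hu=200.0,
        seed=11,
    )
    return spec, pp.make_phantom_ct(spec)


def make_box_mask(vol, half_u=60.0, half_v=60.0, z_range=None):
    """Axis-aligned box ROI on a volume's grid (|x|,|y| bounds, optional z)."""
    xs, ys, zs = vol.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    sel = (np.abs(X) < half_u) & (np.abs(Y) < half_v)
    if z_range is not None:
        sel &= (Z >= z_range[0]) & (Z < z_range[1])
    return pp.ROIMask(sel, vol.spacing_mm, vol.origin_mm)


@pytest.fixture(scope="session")
def noiseless_pair(slab_phantom, beam_z):
    """Noise-free predicted/measured pair with a +3 mm constant shift."""
    spec, (ct, body, clips, art) = slab_phantom
    model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0, amplitude=500.0)
    shifts = pp.ShiftField.constant(3.0)
    pred, meas, truth = pp.generate_activity_pair(
        ct, body, beam_z, model, shifts, noise="none", seed=0
    )
    return ct, body, pred, meas, truth, model


@pytest.fixture(scope="session")
def analysis_grid():
    return pp.make_sampling_grid((-60.0, 60.0), 3.0)
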