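"""Synthetic forward model: CT phantoms with Ti clips, and paired
predicted/measured positron-activity volumes with known range shifts.

The generator emulates what an offline proton-PET verification study
assumes about its data: an activity plateau with a sharp distal falloff
a few cm below the skin, a decay-weighted mixture of short-lived
positron emitters (the scan starts minutes after irradiation), Poisson
counting noise, high-HU clip inclusions with surrounding artifact
shells, and per-region ground-truth range shifts of a few mm.

The depth-activity curve is amplitude * b(z) * L(z) * D with a linear
build-up b(z) = min(z/buildup, 1), a logistic distal falloff
L(z) = 1 / (1 + exp((z - R)/sigma)) and a decay weight D integrating
isotope decays over the acquisition window. The logistic form is chosen
because its half-maximum depth is closed-form (exactly R when the
plateau is flat), giving an analytic test surface; it is a deliberate
stand-in, not a physical emitter-production model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bev import project_mask_to_bev
from .geometry import BeamGeometry, SamplingGrid
from .grids import ROIMask, VolumeGrid
from .ranges import DeltaR50Map

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0

#: standard half-lives (min) of the positron emitters produced by
#: protons in tissue, and field-typical production fractions
DEFAULT_ISOTOPES = {"C11": 20.4, "O15": 2.04, "N13": 9.97}
DEFAULT_FRACTIONS = (0.55, 0.38, 0.07)


@dataclass
class SlabBody:
    """Body occupying ``lo_mm <= coord < hi_mm`` along one axis, the full
    grid extent on the others. Bounds are physical (voxel-center test)."""

    axis: int = 2
    lo_mm: float = 0.0
    hi_mm: float = 150.0
    tissue_hu: float = SOFT_TISSUE_HU


@dataclass
class EllipsoidBody:
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (80.0, 80.0, 80.0)
    tissue_hu: float = SOFT_TISSUE_HU


@dataclass
class Clip:
    """Spherical Ti surgical-clip inclusion."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 2.0
    hu: float = 3000.0


@dataclass
class PhantomSpec:
    """Phantom geometry: grid, body, clips and artifact shells.

    Clip HU must exceed 1500 (the contouring threshold that identifies
    Ti on CT); clip centers must lie inside the body; clips must not
    overlap one another.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 60)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] | None = None
    body: SlabBody | EllipsoidBody = field(default_factory=SlabBody)
    clip_list: list[Clip] = field(default_factory=list)
    artifact_radius_mm: float = 6.0
    streak_hu: float = 0.0  # 0 disables the streak perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive on every axis")
        for clip in self.clip_list:
            if clip.hu <= 1500:
                raise ValueError("clip HU must exceed 1500 (Ti contouring threshold)")
        if self.origin_mm is None:
            # grid centered on the physical origin
            self.origin_mm = tuple(
                -0.5 * (n - 1) * s for n, s in zip(self.grid_shape, self.spacing_mm)
            )


def _body_mask_values(spec: PhantomSpec, xs, ys, zs) -> np.ndarray:
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    body = spec.body
    if isinstance(body, SlabBody):
        coord = (X, Y, Z)[body.axis]
        return (coord >= body.lo_mm) & (coord < body.hi_mm)
    if isinstance(body, EllipsoidBody):
        c, r = body.center_mm, body.radii_mm
        return (((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2
                + ((Z - c[2]) / r[2]) ** 2) <= 1.0
    raise TypeError(f"unsupported body description: {type(body).__name__}")


def make_phantom_ct(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, ROIMask, ROIMask, ROIMask]:
    """Rasterize a phantom: CT volume plus body, clip and artifact masks.

    The CT holds air HU outside the body, the body's soft-tissue HU
    inside, and each clip's HU at clip voxels. The artifact mask is the
    shell of body voxels within ``artifact_radius_mm`` of any clip
    center, excluding clip voxels. When ``streak_hu`` is non-zero a
    deterministic radial +/-streak_hu alternation (seeded spoke phase)
    perturbs the CT inside the artifact shell — a fixture for testing
    the HU-override correction, not a physical artifact model.
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=np.float64)
    origin = np.asarray(spec.origin_mm, dtype=np.float64)
    xs, ys, zs = (origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    body = _body_mask_values(spec, xs, ys, zs)
    ct = np.where(body, getattr(spec.body, "tissue_hu"), AIR_HU).astype(np.float64)

    # overlap check before rasterization
    for i, a in enumerate(spec.clip_list):
        for b in spec.clip_list[i + 1:]:
            d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
            if d < a.radius_mm + b.radius_mm:
                raise ValueError("overlapping clips")

    clip_mask = np.zeros(shape, dtype=bool)
    artifact_mask = np.zeros(shape, dtype=bool)
    for clip in spec.clip_list:
        cx, cy, cz = clip.center_mm
        ci = np.rint((np.asarray(clip.center_mm) - origin) / spacing).astype(int)
        if np.any(ci < 0) or np.any(ci >= np.asarray(shape)) or not body[tuple(ci)]:
            raise ValueError(f"clip center {clip.center_mm} lies outside the body")
        dist2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        clip_mask |= dist2 <= clip.radius_mm**2
        artifact_mask |= (dist2 <= spec.artifact_radius_mm**2) & body
    artifact_mask &= ~clip_mask

    for clip in spec.clip_list:
        cx, cy, cz = clip.center_mm
        sel = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= clip.radius_mm**2
        ct[sel] = clip.hu

    if spec.streak_hu != 0.0 and artifact_mask.any():
        rng = np.random.default_rng(spec.seed)
        phase = rng.uniform(0, 2 * np.pi)
        # nearest clip center per artifact voxel defines the spoke angle
        centers = np.array([c.center_mm for c in spec.clip_list])
        pts = np.stack([X[artifact_mask], Y[artifact_mask], Z[artifact_mask]], axis=1)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        near = centers[np.argmin(d2, axis=1)]
        ang = np.arctan2(pts[:, 1] - near[:, 1], pts[:, 0] - near[:, 0]) + phase
        spoke = np.floor(ang / (np.pi / 8)).astype(int)
        ct[artifact_mask] += spec.streak_hu * np.where(spoke % 2 == 0, 1.0, -1.0)

    mk = lambda v: ROIMask(v, spacing.copy(), origin.copy())
    return (VolumeGrid(ct, spacing, origin), mk(body), mk(clip_mask), mk(artifact_mask))


@dataclass
class ActivityModel:
    """Parameters of the analytic depth-activity curve and the offline
    acquisition timing.

    R_mm : nominal distal range from skin entry (mm); the flat-plateau
        half-maximum depth of the generated profile equals R_mm.
    sigma_mm : logistic falloff width (mm).
    buildup_mm : proximal linear build-up length (mm); 0 gives a flat
        plateau from the skin.
    amplitude : plateau activity before decay weighting (counts).
    isotope_fractions / half_lives_min : positron-emitter mixture.
    delay_min : treatment-to-scan transport interval (min).
    scan_min : acquisition duration (min).
    """

    R_mm: float = 40.0
    sigma_mm: float = 3.0
    buildup_mm: float = 5.0
    amplitude: float = 500.0
    isotope_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    half_lives_min: tuple[float, ...] = tuple(DEFAULT_ISOTOPES.values())
    delay_min: float = 10.4
    scan_min: float = 30.0

    def __post_init__(self) -> None:
        if self.R_mm <= 0 or self.sigma_mm <= 0:
            raise ValueError("R_mm and sigma_mm must be positive")
        if self.buildup_mm < 0:
            raise ValueError("buildup_mm must be non-negative")
        f = np.asarray(self.isotope_fractions, dtype=np.float64)
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("isotope_fractions must sum to 1")
        if len(self.isotope_fractions) != len(self.half_lives_min):
            raise ValueError("one half-life per isotope fraction required")
        if not all(h > 0 for h in self.half_lives_min):
            raise ValueError("half-lives must be positive")


def decay_weight(model: ActivityModel) -> float:
    """Fraction of produced positron emitters decaying inside the scan
    window: sum_i f_i * (exp(-lam_i*t_d) - exp(-lam_i*(t_d + T))) with
    lam_i = ln2 / half_life_i, delay t_d and scan duration T.

    Strictly decreasing in the delay for any fixed mixture — the longer
    the transport to the scanner, the fewer counts survive.
    """
    if model.delay_min < 0 or model.scan_min < 0:
        raise ValueError("delay and scan duration must be non-negative")
    f = np.asarray(model.isotope_fractions, dtype=np.float64)
    lam = np.log(2.0) / np.asarray(model.half_lives_min, dtype=np.float64)
    return float(np.sum(f * (np.exp(-lam * model.delay_min)
                             - np.exp(-lam * (model.delay_min + model.scan_min)))))


def depth_activity(z, model: ActivityModel, range_shift_mm=0.0):
    """Activity at depth(s) ``z`` mm from skin entry.

    ``range_shift_mm`` shifts the nominal range R_mm (used to impose
    ground-truth shifts on the measured volume). Accepts scalars or
    arrays; z must be non-negative.
    """
    z = np.asarray(z, dtype=np.float64)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    if model.buildup_mm == 0:
        b = 1.0
    else:
        b = np.minimum(z / model.buildup_mm, 1.0)
    R = model.R_mm + range_shift_mm
    L = 1.0 / (1.0 + np.exp((z - R) / model.sigma_mm))
    out = model.amplitude * b * L * decay_weight(model)
    return float(out) if out.ndim == 0 else out


@dataclass
class ShiftField:
    """Ground-truth range shift delta(u, v) over the BEV plane, plus a
    global activity scale between measured and predicted.

    Piecewise-constant: axis-aligned (u, v) rectangles override a
    default shift; later rectangles win. Positive delta means the
    measured falloff is deeper than predicted, so the analysis should
    recover a range difference of -delta.
    """

    default_delta_mm: float = 0.0
    rectangles: list[tuple[float, float, float, float, float]] = field(
        default_factory=list
    )  # (u_min, u_max, v_min, v_max, delta_mm)
    global_scale: float = 1.0
    max_abs_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        deltas = [self.default_delta_mm] + [r[4] for r in self.rectangles]
        if any(abs(d) > self.max_abs_mm for d in deltas):
            raise ValueError(f"|delta| exceeds the configured maximum "
                             f"{self.max_abs_mm} mm")

    @classmethod
    def constant(cls, delta_mm: float, global_scale: float = 1.0) -> "ShiftField":
        return cls(default_delta_mm=delta_mm, global_scale=global_scale)

    def delta(self, u, v):
        """Vectorized delta(u, v) in mm."""
        u = np.asarray(u, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        out = np.full(np.broadcast(u, v).shape, self.default_delta_mm)
        for (u0, u1, v0, v1, d) in self.rectangles:
            out[(u >= u0) & (u < u1) & (v >= v0) & (v < v1)] = d
        return out


def _voxel_depth_field(
    body_mask: ROIMask, geom: BeamGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (depth-from-skin, u, v) along the beam.

    Voxels are binned into BEV cells at the voxel pitch; the entry of a
    cell is the minimum along-beam coordinate of its body voxels, so a
    voxel's depth is its along-beam coordinate minus its cell's entry.
    Exact for axis-aligned beams on slab-like bodies; a voxel-pitch
    approximation for oblique beams.
    """
    xs, ys, zs = (
        body_mask.origin_mm[a] + np.arange(body_mask.shape[a]) * body_mask.spacing_mm[a]
        for a in range(3)
    )
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    uvs = geom.world_to_bev(pts)
    u, v, s = uvs[:, 0], uvs[:, 1], uvs[:, 2]

    pitch = float(body_mask.spacing_mm.min())
    iu = np.rint(u / pitch).astype(np.int64)
    iv = np.rint(v / pitch).astype(np.int64)
    key = iu - iu.min() + (iu.max() - iu.min() + 1) * (iv - iv.min())
    _, inv = np.unique(key, return_inverse=True)
    body_flat = body_mask.values.ravel()

    entry = np.full(inv.max() + 1, np.inf)
    np.minimum.at(entry, inv[body_flat], s[body_flat])
    depth = s - entry[inv]
    depth[~body_flat] = np.nan
    shape = body_mask.shape
    return depth.reshape(shape), u.reshape(shape), v.reshape(shape)


def generate_activity_pair(
    ct: VolumeGrid,
    body_mask: ROIMask,
    geom: BeamGeometry,
    model: ActivityModel,
    shifts: ShiftField,
    noise: str = "none",
    seed: int = 0,
    truth_grid: SamplingGrid | None = None,
) -> tuple[VolumeGrid, VolumeGrid, DeltaR50Map]:
    """Generate a predicted/measured activity-volume pair with known
    ground-truth range shifts.

    The predicted volume follows the depth-activity curve with depth
    measured from the body's skin entry along the beam; the measured
    volume uses range R_mm + delta(u, v) and the global activity scale,
    with optional Poisson sampling. The returned truth map records
    -delta(u, v) per BEV cell of ``truth_grid`` (default: 3 mm pitch
    over the body footprint) — the range difference the analysis should
    recover, since it reports predicted minus measured falloff depth.
    The truth map depends only on the shift field, never on the noise
    realization.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    if not body_mask.values.any():
        raise ValueError("body mask is empty")
    depth, u, v = _voxel_depth_field(body_mask, geom)
    if not np.isfinite(depth[body_mask.values]).any():
        raise ValueError("beam misses the body entirely")

    inside = body_mask.values
    d_in = depth[inside]
    predicted = np.zeros(ct.shape, dtype=np.float64)
    predicted[inside] = depth_activity(d_in, model)

    delta = shifts.delta(u[inside], v[inside])
    measured = np.zeros(ct.shape, dtype=np.float64)
    measured[inside] = shifts.global_scale * depth_activity(
        d_in, model, range_shift_mm=delta
    )
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        measured = rng.poisson(measured).astype(np.float64)

    if truth_grid is None:
        uv_body = geom.world_to_bev(
            np.stack(np.nonzero(inside), axis=1) * body_mask.spacing_mm
            + body_mask.origin_mm
        )
        lo = uv_body[:, :2].min(axis=0)
        hi = uv_body[:, :2].max(axis=0)
        truth_grid = SamplingGrid(((lo[0], hi[0] + 3.0), (lo[1], hi[1] + 3.0)), 3.0)
    anchors = truth_grid.positions
    truth_vals = (-shifts.delta(anchors[:, 0], anchors[:, 1])).reshape(truth_grid.shape)
    in_field = project_mask_to_bev(body_mask, geom, truth_grid)
    truth = DeltaR50Map(values=truth_vals, valid=in_field, grid=truth_grid)

    pred_vol = ct.copy_with(predicted)
    meas_vol = ct.copy_with(measured)
    return pred_vol, meas_vol, truth
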