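# Methods

## The problem

In proton therapy the dose is deposited up to a sharp distal edge whose
position depends on the tissue the beam traverses. Titanium surgical
clips implanted after breast-conserving surgery are high-HU objects that
streak the planning CT and can perturb the predicted proton range, so
clinical practice applies a *tissue correction*: clip voxels are
contoured at a HU above the Ti threshold (>1500) and the surrounding
artifact region is reclassified to adipose. Offline PET imaging — a scan
started minutes after irradiation — measures the spatial distribution of
the positron emitters (¹¹C, ¹⁵O, ¹³N) produced by nuclear interactions
of the beam; the *distal falloff of that activity* is a surrogate for
beam range. Comparing a predicted activity volume against the measured
one, depth profile by depth profile, verifies in vivo whether the
delivered range matched the plan near the clips.

This package implements that comparison, plus a synthetic forward model
that manufactures volume pairs with *known* range shifts so every stage
of the analysis can be verified quantitatively without patient data.

## The R50 statistic

For a beam-parallel line through BEV anchor (u, v), activity is sampled
by trilinear interpolation at a uniform step (default 1 mm) from the
skin entry until the line exits the body. With profile maximum V_max,
the half-maximum is V50 = V_max / 2 and

  R50 = depth of the **distal-most** crossing of V50,

linearly interpolated between the bracketing samples. The distal-most
crossing (not the first) is used deliberately: a clip or artifact can
dip a profile below half-max *proximally*, and such dips must not
capture the half-max — only the terminal falloff carries range
information. The per-line range difference is

  ΔR50 = R50(predicted) − R50(measured),

so a **negative ΔR50 means the measured falloff is deeper than
predicted**. Because V50 is relative to each profile's own peak, ΔR50 is
invariant under any positive rescaling of either volume; normalization
therefore cannot change noiseless results (this is tested).

Lines whose peak falls below `min_peak_frac` (default 0.10) of the
BEV-wide maximum of the same image are flagged invalid rather than
producing a meaningless half-max; the clinical protocol states no
exclusion rule, so the threshold is exposed as a parameter.

## Geometry conventions

* Volumes are axis-aligned regular grids, arrays indexed `(x, y, z)`,
  physical mm coordinates, voxel-center origin, 0-based indices.
* The BEV basis is built from the beam direction d as
  u = normalize(d × superior), v = d × u (right-handed, u × v = d). The
  in-plane orientation is arbitrary — ΔR50 statistics are rotation
  invariant in the BEV plane.
* The sampling lattice is **half-open**: anchors at min + k·pitch for
  k = 0 … ⌈(max−min)/pitch⌉−1 per axis. With the clinical extent
  (−120 mm, 120 mm) and 3 mm pitch this yields exactly 80 × 80 = 6400
  lines; a closed interval would not.
* **Skin entry / depth 0** is the first voxel center along the beam
  whose body-mask value is true. The membership crossing is located by
  a coarse scan (half the smallest voxel dimension) refined by
  bisection, then the entry is that voxel center's projection onto the
  line. Clip "skin depth" uses the same convention. Any constant
  per-line entry offset cancels in ΔR50, which compares two volumes
  along the same line.

## Preprocessing

* **Smoothing**: sliding-window mean, window 3×3 or 5×5, stride 1, zero
  padding with the divisor fixed at the full window size (edge voxels
  are attenuated, not renormalized). Applied slice-wise in the axial
  plane by default — the printed window shapes are 2D — with a full-3D
  option. By default only the measured image is smoothed; the predicted
  image is treated as noise-free. The implementation accumulates
  shifted copies in row-major window order, which makes it bit-identical
  to a per-pixel double loop in double precision.
* **Normalization**: the measured image is multiplied by
  mean(predicted | target) / mean(measured | target). The target area
  defaults to the PTV (configurable to the boost volume; the protocol
  does not name the structure). Idempotent, and a no-op for ΔR50.
* **HU override**: clip voxels → `ti_hu` (default 3000, must exceed the
  1500 Ti threshold); artifact-shell voxels → `adipose_hu` (default
  −100). Masks must be disjoint; idempotent.
* **Rigid translation**: trilinear resampling at positions shifted by
  −t; only application of a given translation is supported (used by the
  translation-equivariance test), not registration itself.

## Clip-region analysis

Each clip's mask is projected onto the BEV (a cell is inside the
footprint iff its line intersects the mask); the footprint's bounding
region is re-anchored at a **1 mm fine pitch**, anchors whose nearest
coarse cell lies in the footprint are kept, and the per-clip statistic
is the mean of per-line ΔR50 over valid fine lines (per-line differences
are averaged, not per-line depths). Clips are grouped by skin depth with
a 2 cm boundary — exactly 20 mm joins the deep group, since the groups
are defined by strict inequalities and the boundary is otherwise
unassigned. The rationale for the boundary: the activity half-max sits
2–3 cm below the skin, so clips deeper than the half-max position cannot
influence the crossing.

The **control ROI** is the clip mask translated 10 mm along the 3D unit
vector from the clip centroid to the boost-volume centroid, re-rasterized
to the nearest voxel (the translation is quantized by up to half a voxel
per axis). It samples adjacent normal tissue with an equal footprint.

Group comparison uses the independent-samples t-test: pooled-variance
Student's t by default (df = nₐ+n_b−2), matching the conventional
clinical "Independent Samples T-Test"; Welch's variant is available by
flag. The 0.05 significance level is reported but never gates any
computation, and no multiple-testing correction is applied (none is in
the protocol being modeled).

## Synthetic forward model

The generator emulates the statistical structure the analysis assumes,
not the physics of emitter production:

* **Depth-activity curve**: a(z) = A · b(z) · L(z) · D with linear
  build-up b(z) = min(z/z_b, 1), logistic falloff
  L(z) = 1/(1 + exp((z − R)/σ)) and decay weight D. The logistic is
  chosen because its half-max depth is closed-form (exactly R when the
  plateau is flat), giving an analytic test surface. It is a deliberate
  stand-in for an activity-prediction engine, not a reconstruction of
  one.
* **Decay weight**: D = Σᵢ fᵢ (e^(−λᵢ t_d) − e^(−λᵢ (t_d+T))),
  λᵢ = ln2/T½ᵢ — the fraction of produced emitters decaying inside the
  acquisition window. Defaults: delay t_d = 10.4 min (the mean clinical
  transport interval), scan T = 30 min, isotopes ¹¹C/¹⁵O/¹³N with
  standard half-lives 20.4/2.04/9.97 min and production fractions
  0.55/0.38/0.07 (field-typical soft-tissue values; the protocol names
  the isotopes but not fractions). D is strictly decreasing in the
  delay.
* **Ground-truth shifts**: the measured volume uses range R + δ(u, v)
  with δ piecewise-constant over BEV rectangles (|δ| ≤ 10 mm by
  default) and an optional global activity scale; optional Poisson
  sampling adds counting noise. The truth map records −δ per BEV cell —
  exactly what ΔR50 should recover — and depends only on the shift
  field, never on the noise realization.
* **Phantom**: slab or ellipsoid body (soft tissue 40 HU, air −1000),
  spherical clips (default 3000 HU), an artifact shell within a
  configurable radius of each clip center, and an optional deterministic
  ±HU radial streak pattern inside the shell (a fixture for testing the
  HU override, not a physical artifact model).
* Per-voxel depth is computed by binning voxels into BEV cells at the
  voxel pitch and subtracting each cell's minimum along-beam body
  coordinate — exact for axis-aligned beams on slab-like bodies (the
  test geometry), a voxel-pitch approximation for oblique beams.

What the generator does **not** emulate: nuclear cross-sections and
Monte Carlo transport, spot-by-spot delivery timing, scanner/detector
response and reconstruction, biological washout, registration error.
Passing tests therefore demonstrate the correctness of the *analysis*
under its stated assumptions (co-registered volumes, falloff within the
grid, shift constant per line), not the fidelity of any activity
prediction on real patients.

## Numerical choices

* Trilinear interpolation throughout (`scipy.ndimage`, order 1, zero
  outside support); no spline prefiltering.
* Line tracing: coarse membership scan at half the smallest voxel
  dimension, 20 bisection iterations (~10⁻⁶ of the scan step).
* R50 interpolation guards against flat segments (the crossing
  condition v[i] ≥ V50 > v[i+1] makes the denominator positive).
* Profiles are padded one step beyond the body exit; samples outside
  the volume are zero, so a falloff truncated by the grid boundary still
  yields a crossing at the boundary (choose grids deep enough that the
  falloff fits — the generator defaults place R = 40–60 mm in bodies
  ≥ 145 mm deep).
* Report JSON is written with sorted keys so identical inputs produce
  byte-identical summaries.

## Problem sizes in the test and acceptance runs

Noiseless shift-recovery runs use an 80×80×60 voxel grid at 3 mm
(matching the 3 mm PET voxel size of the modeled protocol) with a
60×60-line BEV lattice; stochastic per-clip recovery uses a 60×60×49
grid with three 4 mm clips, a 500-count post-decay plateau ("plateau
500 counts" is interpreted post-decay, since Poisson statistics act on
actual acquired counts: the model amplitude is set to 500/D), 1 mm fine
pitch and five noise seeds. These sizes keep the full verification
suite in the tens of seconds while leaving every per-line tolerance
(0.1 mm noiseless, 0.5 mm per-clip stochastic) comfortably resolved.

## Known limitations

* Parallel-line geometry only; divergent (fan/cone) beams are out of
  scope. Multi-field plans are analyzed one field at a time.
* Registration is assumed done: only application of a given rigid
  translation is provided.
* Orientation matrices in NIfTI/NRRD headers beyond axis ordering are
  not interpreted; volumes must be axis-aligned.
* The per-clip mean averages per-line ΔR50, which weights each valid
  line equally regardless of its activity level.
* Clips modeled as spheres; real clips are elongated. The BEV footprint
  logic does not depend on clip shape.
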