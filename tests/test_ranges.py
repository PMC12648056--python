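"""R50 extraction, dR50 maps, clip-region refinement, control ROI."""

import numpy as np
import pytest

import protonpet as pp
from protonpet.bev import DepthProfile
from protonpet.grids import ROIMask


def logistic_profile(R=60.0, sigma=3.0, step=1.0, span=140.0, noise=None, seed=0):
    z = np.arange(0.0, span, step)
    v = 1.0 / (1.0 + np.exp((z - R) / sigma))
    if noise is not None:
        rng = np.random.default_rng(seed)
        v = np.clip(v + rng.normal(0, noise, size=v.shape), 0, None)
    return DepthProfile(z, v, (0.0, 0.0))


def brute_force_distal_r50(profile, step=0.001):
    """Independent oracle: scan the piecewise-linear interpolant of the
    profile at 1 um resolution for the distal-most half-max crossing."""
    z = np.arange(profile.depths_mm[0], profile.depths_mm[-1], step)
    v = np.interp(z, profile.depths_mm, profile.values)
    v50 = profile.values.max() / 2
    above = v >= v50
    cross = np.nonzero(above[:-1] & ~above[1:])[0]
    return z[cross[-1]] if len(cross) else np.nan


class TestComputeR50:
    def test_step_profile_interpolated_midpoint(self):
        prof = DepthProfile(np.array([0.0, 1, 2, 3, 4]),
                            np.array([1.0, 1, 1, 0, 0]), (0, 0))
        res = pp.compute_r50(prof)
        assert res.valid
        assert res.v_50 == 0.5
        assert np.isclose(res.r50_mm, 2.5)

    @pytest.mark.parametrize("R,sigma", [(30.0, 1.0), (60.0, 3.0), (90.0, 5.0)])
    def test_flat_plateau_logistic_half_max_at_R(self, R, sigma):
        res = pp.compute_r50(logistic_profile(R, sigma, step=1.0, span=2 * R))
        assert res.valid
        assert abs(res.r50_mm - R) < 0.05

    def test_noisy_profiles_match_fine_scan_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            R = rng.uniform(30, 90)
            sigma = rng.uniform(1, 5)
            prof = logistic_profile(R, sigma, noise=0.02,
                                    seed=int(rng.integers(1 << 30)))
            res = pp.compute_r50(prof)
            expected = brute_force_distal_r50(prof)
            assert res.valid
            assert abs(res.r50_mm - expected) < 0.01

    def test_proximal_dip_does_not_capture_half_max(self):
        # a clip-induced dip below half-max upstream of the falloff must
        # be ignored: the distal-most crossing defines R50
        z = np.arange(0.0, 100.0)
        v = np.where(z < 80, 10.0, 0.0)
        v[20:23] = 1.0  # proximal dip below half-max
        res = pp.compute_r50(DepthProfile(z, v, (0, 0)))
        assert 79.0 < res.r50_mm < 80.0

    def test_below_min_peak_flagged_invalid(self):
        res = pp.compute_r50(logistic_profile(), min_peak=2.0)
        assert not res.valid
        assert np.isnan(res.r50_mm)

    def test_no_distal_crossing_flagged_invalid(self):
        prof = DepthProfile(np.arange(5.0), np.ones(5), (0, 0))
        assert not pp.compute_r50(prof).valid

    def test_invalid_profile_propagates(self):
        prof = DepthProfile(np.zeros(0), np.zeros(0), (0, 0), valid=False)
        assert not pp.compute_r50(prof).valid


class TestDeltaR50:
    def test_identical_profiles_give_zero(self):
        r = pp.compute_r50(logistic_profile())
        assert pp.delta_r50(r, r) == 0.0

    def test_deeper_measured_gives_negative(self):
        calc = pp.compute_r50(logistic_profile(R=60.0))
        meas = pp.compute_r50(logistic_profile(R=62.0))
        assert np.isclose(pp.delta_r50(calc, meas), -2.0, atol=0.01)

    def test_invalid_input_gives_nan(self):
        good = pp.compute_r50(logistic_profile())
        bad = pp.compute_r50(logistic_profile(), min_peak=10.0)
        assert np.isnan(pp.delta_r50(good, bad))
        assert np.isnan(pp.delta_r50(bad, good))


class TestDeltaR50Map:
    def _ptv(self, vol, body):
        from conftest import make_box_mask
        m = make_box_mask(vol, 60.0, 60.0)
        return ROIMask(m.values & body.values, vol.spacing_mm, vol.origin_mm)

    def test_zero_shift_zero_map(self, slab_phantom, beam_z, analysis_grid):
        spec, (ct, body, clips, art) = slab_phantom
        model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0)
        pred, meas, _ = pp.generate_activity_pair(
            ct, body, beam_z, model, pp.ShiftField.constant(0.0), noise="none")
        dmap = pp.delta_r50_map(pred, meas, body, self._ptv(ct, body),
                                beam_z, analysis_grid)
        assert dmap.n_valid > 100
        assert np.allclose(dmap.values[dmap.valid], 0.0)
        assert dmap.sd_mm == 0.0

    @pytest.mark.parametrize("delta", [3.0, -3.0])
    def test_constant_shift_recovered(self, slab_phantom, beam_z,
                                      analysis_grid, delta):
        spec, (ct, body, clips, art) = slab_phantom
        model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0)
        pred, meas, truth = pp.generate_activity_pair(
            ct, body, beam_z, model, pp.ShiftField.constant(delta), noise="none")
        dmap = pp.delta_r50_map(pred, meas, body, self._ptv(ct, body),
                                beam_z, analysis_grid)
        err = np.abs(dmap.values[dmap.valid] - (-delta))
        assert err.max() < 0.1

    def test_piecewise_shift_pattern_reproduced(self, slab_phantom, beam_z,
                                                analysis_grid):
        spec, (ct, body, clips, art) = slab_phantom
        model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0)
        shifts = pp.ShiftField(rectangles=[(-200.0, 0.0, -200.0, 200.0, -3.0),
                                           (0.0, 200.0, -200.0, 200.0, 3.0)])
        pred, meas, truth = pp.generate_activity_pair(
            ct, body, beam_z, model, shifts, noise="none")
        dmap = pp.delta_r50_map(pred, meas, body, self._ptv(ct, body),
                                beam_z, analysis_grid)
        # compare cellwise against the generator truth away from the
        # region boundary (boundary lines interpolate across both regions)
        uu = analysis_grid.positions[:, 0].reshape(analysis_grid.shape)
        away = np.abs(uu) > 3.0
        sel = dmap.valid & away
        expected = -shifts.delta(uu, np.zeros_like(uu))
        assert sel.sum() > 100
        np.testing.assert_allclose(dmap.values[sel], expected[sel], atol=0.1)

    def test_empty_ptv_footprint_rejected(self, slab_phantom, beam_z,
                                          analysis_grid, noiseless_pair):
        _, body, pred, meas, _, _ = noiseless_pair
        empty = ROIMask(np.zeros(body.shape, dtype=bool), body.spacing_mm,
                        body.origin_mm)
        with pytest.raises(ValueError):
            pp.delta_r50_map(pred, meas, body, empty, beam_z, analysis_grid)

    def test_scale_invariance_of_dr50(self, noiseless_pair, beam_z, analysis_grid):
        # half-max is relative: rescaling the measured image leaves every
        # dR50 unchanged, so normalization cannot alter noiseless results
        ct, body, pred, meas, _, _ = noiseless_pair
        ptv = self._ptv(ct, body)
        d1 = pp.delta_r50_map(pred, meas, body, ptv, beam_z, analysis_grid)
        scaled = meas.copy_with(meas.values * 7.3)
        d2 = pp.delta_r50_map(pred, scaled, body, ptv, beam_z, analysis_grid)
        np.testing.assert_array_equal(d1.valid, d2.valid)
        np.testing.assert_allclose(d1.values[d1.valid], d2.values[d2.valid],
                                   atol=1e-9)

    def test_translation_equivariance(self, noiseless_pair, beam_z, analysis_grid):
        # shifting the measured volume deeper by t moves R50meas by +t,
        # hence every dR50 by -t
        ct, body, pred, meas, _, _ = noiseless_pair
        ptv = self._ptv(ct, body)
        base = pp.delta_r50_map(pred, meas, body, ptv, beam_z, analysis_grid)
        for t in (-3.0, 3.0):
            shifted = pp.apply_rigid_translation(meas, t * beam_z.direction)
            dm = pp.delta_r50_map(pred, shifted, body, ptv, beam_z, analysis_grid)
            sel = base.valid & dm.valid
            diff = dm.values[sel] - base.values[sel]
            assert np.abs(diff - (-t)).max() < 0.1


class TestClipRegionDR50:
    def test_zero_shift_zero_mean(self, slab_phantom, beam_z, analysis_grid):
        spec, (ct, body, clips, art) = slab_phantom
        model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0)
        pred, meas, _ = pp.generate_activity_pair(
            ct, body, beam_z, model, pp.ShiftField.constant(0.0), noise="none")
        fp = pp.project_mask_to_bev(clips, beam_z, analysis_grid)
        mean, n = pp.clip_region_dr50(pred, meas, body, fp, analysis_grid, beam_z)
        assert n > 10
        assert abs(mean) < 1e-6

    def test_constant_shift_recovered_at_fine_pitch(self, slab_phantom, beam_z,
                                                    analysis_grid):
        spec, (ct, body, clips, art) = slab_phantom
        model = pp.ActivityModel(R_mm=60.0, sigma_mm=3.0, buildup_mm=5.0)
        pred, meas, _ = pp.generate_activity_pair(
            ct, body, beam_z, model, pp.ShiftField.constant(2.0), noise="none")
        fp = pp.project_mask_to_bev(clips, beam_z, analysis_grid)
        mean, _ = pp.clip_region_dr50(pred, meas, body, fp, analysis_grid, beam_z)
        assert abs(mean - (-2.0)) < 0.1

    def test_single_cell_footprint_equals_single_line(self, noiseless_pair,
                                                      beam_z, analysis_grid):
        ct, body, pred, meas, _, _ = noiseless_pair
        fp = np.zeros(analysis_grid.shape, dtype=bool)
        fp[20, 20] = True
        # fine pitch equal to the coarse pitch -> exactly one line
        mean, n = pp.clip_region_dr50(pred, meas, body, fp, analysis_grid,
                                      beam_z, fine_pitch_mm=3.0)
        assert n == 1
        anchor = analysis_grid.positions[20 * analysis_grid.shape[1] + 20]
        p1 = pp.extract_profile(pred, body, beam_z, tuple(anchor), step_mm=1.0)
        p2 = pp.extract_profile(meas, body, beam_z, tuple(anchor), step_mm=1.0)
        expected = pp.delta_r50(pp.compute_r50(p1), pp.compute_r50(p2))
        assert np.isclose(mean, expected, atol=1e-6)

    def test_empty_footprint_rejected(self, noiseless_pair, beam_z, analysis_grid):
        ct, body, pred, meas, _, _ = noiseless_pair
        with pytest.raises(ValueError):
            pp.clip_region_dr50(pred, meas, body,
                                np.zeros(analysis_grid.shape, dtype=bool),
                                analysis_grid, beam_z)


class TestControlROI:
    def _masks(self, clip_at, boost_at, shape=(40, 40, 40), spacing=2.0):
        origin = tuple(-0.5 * (n - 1) * spacing for n in shape)
        sp = (spacing,) * 3
        xs = [origin[a] + np.arange(shape[a]) * spacing for a in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        clip = ((X - clip_at[0]) ** 2 + (Y - clip_at[1]) ** 2
                + (Z - clip_at[2]) ** 2) <= 6.0**2
        boost = ((X - boost_at[0]) ** 2 + (Y - boost_at[1]) ** 2
                 + (Z - boost_at[2]) ** 2) <= 16.0**2
        return ROIMask(clip, sp, origin), ROIMask(boost, sp, origin)

    def test_shift_moves_toward_boost(self):
        clip, boost = self._masks((-10.0, 0.0, 0.0), (20.0, 0.0, 0.0))
        ctrl = pp.make_control_roi(clip, boost, shift_mm=10.0)
        moved = ctrl.centroid_mm() - clip.centroid_mm()
        np.testing.assert_allclose(moved, [10.0, 0.0, 0.0], atol=1.0)

    def test_zero_shift_is_identity(self):
        clip, boost = self._masks((-10.0, 0.0, 0.0), (20.0, 0.0, 0.0))
        ctrl = pp.make_control_roi(clip, boost, shift_mm=0.0)
        np.testing.assert_array_equal(ctrl.values, clip.values)

    def test_centroid_displaced_by_shift_toward_boost(self):
        clip, boost = self._masks((-8.0, 6.0, -4.0), (14.0, -10.0, 12.0))
        ctrl = pp.make_control_roi(clip, boost, shift_mm=10.0)
        d = boost.centroid_mm() - clip.centroid_mm()
        expected = clip.centroid_mm() + 10.0 * d / np.linalg.norm(d)
        # nearest-voxel re-rasterization quantizes the common translation
        # by up to half a voxel per axis (sqrt(3)/2 voxel in norm)
        assert np.linalg.norm(ctrl.centroid_mm() - expected) \
            < np.sqrt(3) * 0.5 * 2.0 + 1e-9

    def test_voxel_count_preserved_within_10_percent(self):
        clip, boost = self._masks((-8.0, 6.0, -4.0), (14.0, -10.0, 12.0))
        ctrl = pp.make_control_roi(clip, boost, shift_mm=10.0)
        assert abs(ctrl.count - clip.count) <= 0.1 * clip.count

    def test_coincident_centroids_rejected(self):
        clip, boost = self._masks((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            pp.make_control_roi(clip, boost)


class TestClassifyClip:
    @pytest.mark.parametrize("depth,group", [
        (15.0, "lt2cm"),
        (20.0, "gt2cm"),  # exact boundary joins the deep group
        (35.0, "gt2cm"),
    ])
    def test_two_cm_boundary(self, depth, group):
        assert pp.classify_clip(depth) == group
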