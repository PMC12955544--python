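"""Line profiles, FWHM estimation and the resolution-vs-diameter curve."""

import numpy as np
import pytest

import nemaiq as nq
from nemaiq.profiles import UndefinedFWHMError
from _oracles import SIGMA_PER_FWHM, sphere_gauss_fwhm


def _gaussian_volume(grid, center, fwhm, amplitude=1.0):
    sig = fwhm * SIGMA_PER_FWHM
    z, y, x = grid.coord_arrays()
    r2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    return nq.Volume(grid, amplitude * np.exp(-r2 / (2 * sig ** 2)), "dimensionless")


class TestLineProfile:
    def test_unblurred_sphere_plateau_and_width(self, cold_spec, fine_cold_truth):
        s = cold_spec.spheres[0]  # 37 mm
        prof = nq.line_profile(fine_cold_truth, s.center, half_length_mm=35)
        assert prof.max == pytest.approx(236.0, rel=1e-6)
        assert nq.fwhm(prof) == pytest.approx(37.0, abs=1.0)

    def test_symmetry_of_blurred_profile(self, cold_spec, fine_cold_truth):
        blurred = nq.blur_model(fine_cold_truth, 8.4)
        prof = nq.line_profile(blurred, cold_spec.spheres[0].center,
                               half_length_mm=35)
        np.testing.assert_allclose(prof.values, prof.values[::-1],
                                   atol=0.01 * prof.max)

    def test_gaussian_point_source_closed_form(self):
        grid = nq.VoxelGrid((41, 41, 41), (1.0, 1.0, 1.0))
        vol = _gaussian_volume(grid, (0, 0, 0), fwhm=8.0)
        prof = nq.line_profile(vol, (0, 0, 0), half_length_mm=15, step_mm=1.0)
        sig = 8.0 * SIGMA_PER_FWHM
        expected = np.exp(-prof.positions_mm ** 2 / (2 * sig ** 2))
        np.testing.assert_allclose(prof.values, expected, atol=0.01)

    def test_default_step_half_voxel_and_monotone_positions(self, fine_cold_truth):
        prof = nq.line_profile(fine_cold_truth, (0, 0, 57.2), half_length_mm=20)
        assert np.diff(prof.positions_mm) == pytest.approx(0.5)

    def test_segment_outside_volume_rejected(self, fine_cold_truth):
        with pytest.raises(ValueError, match="exits"):
            nq.line_profile(fine_cold_truth, (0, 0, 57.2), half_length_mm=500)

    def test_normalization_record(self, fine_cold_truth):
        prof = nq.line_profile(fine_cold_truth, (0, 0, 57.2), half_length_mm=20)
        assert prof.normalization == "raw"
        normed = prof.normalized(236.0)
        assert normed.normalization == "true-concentration"
        assert normed.max == pytest.approx(prof.max / 236.0)
        with pytest.raises(ValueError):
            prof.normalized(0.0)


class TestFWHM:
    def test_gaussian_identity(self):
        # sigma 3.567 mm <-> FWHM 8.40 mm
        pos = np.arange(-30, 30.25, 0.25)
        vals = np.exp(-pos ** 2 / (2 * 3.567 ** 2))
        prof = nq.LineProfile(pos, vals, (0, 0, 0), (0, 0, 1))
        assert nq.fwhm(prof) == pytest.approx(8.40, abs=0.02)

    def test_tophat_width(self):
        pos = np.arange(-30, 30.5, 0.5)
        vals = (np.abs(pos) <= 10.0).astype(float)
        prof = nq.LineProfile(pos, vals, (0, 0, 0), (0, 0, 1))
        assert nq.fwhm(prof) == pytest.approx(20.0, abs=0.5)

    def test_baseline_shifts_result(self):
        pos = np.arange(-30, 30.5, 0.5)
        vals = 5.0 + np.exp(-pos ** 2 / (2 * 4.0 ** 2))
        prof = nq.LineProfile(pos, vals, (0, 0, 0), (0, 0, 1))
        assert nq.fwhm(prof, baseline=5.0) == pytest.approx(4.0 * 2.3548, abs=0.05)

    def test_peak_below_baseline_raises(self):
        pos = np.arange(-5, 5.5, 0.5)
        prof = nq.LineProfile(pos, np.full_like(pos, 2.0), (0, 0, 0), (0, 0, 1))
        with pytest.raises(UndefinedFWHMError):
            nq.fwhm(prof, baseline=3.0)

    def test_blurred_small_sphere_wider_than_true(self, cold_spec, fine_cold_truth):
        # resolution-limited regime: a 10-mm sphere under an 8.4-mm blur
        # appears larger than its true size
        blurred = nq.blur_model(fine_cold_truth, 8.4)
        prof = nq.line_profile(blurred, cold_spec.spheres[5].center,
                               half_length_mm=30)
        assert nq.fwhm(prof) > 10.0


class TestParameterRecovery:
    @pytest.mark.parametrize("fwhm_mm", [3.0, 6.0, 9.0, 12.0])
    def test_point_source_blur_recovered(self, fwhm_mm):
        # FWHM of a blurred point source recovers the blur within 3%
        # (blurs of at least 2 voxels on a 1-mm grid)
        grid = nq.VoxelGrid((48, 48, 48), (1.0, 1.0, 1.0))
        vals = np.zeros(grid.shape)
        vals[24, 24, 24] = 1.0
        img = nq.blur_model(nq.Volume(grid, vals, "kBq/mL"), fwhm_mm)
        prof = nq.line_profile(img, (grid.axis_coords(0)[24],
                                     grid.axis_coords(1)[24],
                                     grid.axis_coords(2)[24]),
                               half_length_mm=20)
        assert nq.fwhm(prof) == pytest.approx(fwhm_mm, rel=0.03)

    def test_apparent_size_matches_closed_form(self, cold_spec, fine_cold_truth):
        # measured apparent size vs the analytic blurred-sphere FWHM,
        # every sphere, two blur levels
        for f in (8.4, 12.0):
            blurred = nq.blur_model(fine_cold_truth, f)
            for s in cold_spec.spheres:
                width = nq.fwhm(nq.line_profile(blurred, s.center,
                                                half_length_mm=s.radius + 25))
                assert width == pytest.approx(sphere_gauss_fwhm(s.diameter, f),
                                              rel=0.02)

    def test_apparent_size_monotone_in_resolution_limited_regime(
            self, cold_spec, fine_cold_truth):
        # once the blur dominates the object (blur >~ diameter), wider
        # blur means larger apparent size; at light blur the apparent
        # size can dip below the true diameter (the peak drops faster
        # than the wings widen), so monotonicity is only tested here
        center = cold_spec.spheres[5].center  # 10 mm
        widths = []
        for f in (8.4, 12.0, 16.0):
            blurred = nq.blur_model(fine_cold_truth, f)
            widths.append(nq.fwhm(nq.line_profile(blurred, center,
                                                  half_length_mm=35)))
        assert widths[0] < widths[1] < widths[2]


class TestResolutionCurve:
    def test_unblurred_truth_on_identity_line(self, cold_spec, fine_cold_truth):
        curve = nq.resolution_curve(fine_cold_truth, cold_spec)
        np.testing.assert_allclose(curve.apparent_mm, curve.diameters_mm, atol=1.0)
        assert not curve.flagged.any()

    def test_light_blur_follows_identity(self, cold_spec, fine_cold_truth):
        # PET-like 2-mm blur: every sphere stays within 5% of the ideal
        # size-equals-diameter line (closed form: worst case 2.9%)
        blurred = nq.blur_model(fine_cold_truth, 2.0)
        curve = nq.resolution_curve(blurred, cold_spec, deviation_threshold=0.10)
        np.testing.assert_allclose(curve.apparent_mm, curve.diameters_mm, rtol=0.05)
        assert not curve.flagged.any()

    def test_heavy_blur_resolution_floor(self, cold_spec, fine_cold_truth):
        # SPECT-like 12-mm blur: the three smallest spheres read nearly
        # the same apparent size regardless of true diameter (closed
        # form: 17.3% spread), and the smallest sits far above identity
        blurred = nq.blur_model(fine_cold_truth, 12.0)
        curve = nq.resolution_curve(blurred, cold_spec)
        small = curve.apparent_mm[-3:]
        assert (small.max() - small.min()) / small.max() < 0.20
        assert curve.apparent_mm[-1] > 1.25 * curve.diameters_mm[-1]
        assert curve.flagged[-1]

    def test_profile_maxima_decline_with_diameter(self, cold_spec, fine_cold_truth):
        blurred = nq.blur_model(fine_cold_truth, 10.0)
        profs = nq.sphere_profiles(blurred, cold_spec)
        maxima = [profs[d].max for d in sorted(profs, reverse=True)]
        assert all(a >= b for a, b in zip(maxima, maxima[1:]))

    def test_warm_background_warns(self, warm_spec, fine_warm_truth):
        blurred = nq.blur_model(fine_warm_truth, 4.0)
        with pytest.warns(UserWarning, match="cold"):
            nq.resolution_curve(blurred, warm_spec)


class TestMaxRelativeIntensityDifference:
    def test_identical_profiles_zero(self, cold_spec, fine_cold_truth):
        prof = nq.line_profile(fine_cold_truth, cold_spec.spheres[0].center,
                               half_length_mm=30)
        table = nq.max_relative_intensity_difference({37.0: prof, 10.0: prof},
                                                     reference=236.0)
        assert table["difference_percent"].iloc[0] == 0.0

    def test_half_maximum_gives_fifty_percent(self):
        pos = np.arange(-10, 10.5, 0.5)
        big = nq.LineProfile(pos, np.exp(-pos ** 2 / 8), (0, 0, 0), (0, 0, 1))
        small = nq.LineProfile(pos, 0.5 * np.exp(-pos ** 2 / 8), (0, 0, 0), (0, 0, 1))
        table = nq.max_relative_intensity_difference({20.0: big, 5.0: small},
                                                     reference=1.0)
        assert table["difference_percent"].iloc[0] == pytest.approx(50.0)

    def test_blur_regimes_split(self, cold_spec, fine_cold_truth):
        # heavy blur: largest-vs-smallest maxima differ by > 80%;
        # light blur: by < 25%
        heavy = nq.sphere_profiles(nq.blur_model(fine_cold_truth, 12.0), cold_spec)
        light = nq.sphere_profiles(nq.blur_model(fine_cold_truth, 3.0), cold_spec)
        t_heavy = nq.max_relative_intensity_difference(heavy, reference=236.0)
        t_light = nq.max_relative_intensity_difference(light, reference=236.0)

        def pair(t, d1, d2):
            row = t[(t.diameter_large_mm == d1) & (t.diameter_small_mm == d2)]
            return float(row["difference_percent"].iloc[0])

        assert pair(t_heavy, 37.0, 10.0) > 80.0
        assert pair(t_light, 37.0, 10.0) < 25.0

    def test_zero_reference_rejected(self, cold_spec, fine_cold_truth):
        prof = nq.line_profile(fine_cold_truth, cold_spec.spheres[0].center,
                               half_length_mm=30)
        with pytest.raises(ValueError, match="reference"):
            nq.max_relative_intensity_difference({37.0: prof}, reference=0.0)
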