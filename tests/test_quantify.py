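"""Quantitative factor, recovery coefficients and contrast."""

import numpy as np
import pandas as pd
import pytest

import nemaiq as nq
from _oracles import sphere_gauss_mean


class TestQuantitativeFactor:
    def test_reciprocal_identity(self):
        qf = nq.quantitative_factor(1.0, 1.0, 1.0)
        assert qf.value == 1.0
        # the worked dual-head example: Cs 0.005, dt = 64 x 27 s, 0.1106 mL
        qf = nq.quantitative_factor(0.005, 64 * 27.0, 0.1106)
        assert qf.value == pytest.approx(1.0465, abs=1e-3)
        assert qf.value * qf.cs_cps_per_bq * qf.dt_s * qf.v_voxel_ml == \
            pytest.approx(1.0, rel=1e-15)

    def test_reciprocal_scaling(self):
        base = nq.quantitative_factor(0.005, 1728.0, 0.1106)
        assert nq.quantitative_factor(0.010, 1728.0, 0.1106).value == \
            pytest.approx(base.value / 2)
        assert nq.quantitative_factor(0.005, 3456.0, 0.1106).value == \
            pytest.approx(base.value / 2)

    def test_nonpositive_rejected(self):
        for bad in [(0, 1, 1), (1, -2, 1), (1, 1, 0)]:
            with pytest.raises(ValueError):
                nq.quantitative_factor(*bad)

    def test_qf_for_protocol(self, sim_grid, spect_protocol):
        qf = nq.qf_for(spect_protocol, sim_grid)
        assert qf.dt_s == 64 * 27.0
        assert qf.v_voxel_ml == pytest.approx(4.8 ** 3 / 1000.0)


class TestCountsToConcentration:
    def test_zero_and_scaling(self, sim_grid):
        img = nq.Volume(sim_grid, np.zeros(sim_grid.shape), "counts")
        qf = nq.quantitative_factor(1.0, 1.0, 1.0)
        out = nq.counts_to_concentration(img, qf)
        assert out.unit == "kBq/mL"
        assert not out.values.any()
        img = nq.Volume(sim_grid, np.full(sim_grid.shape, 500.0), "counts")
        # QF of 1 Bq/mL per count: values identical in Bq/mL, /1000 in kBq/mL
        out = nq.counts_to_concentration(img, qf)
        np.testing.assert_allclose(out.values * 1000.0, img.values)

    def test_unit_mismatch_rejected(self, sim_grid):
        img = nq.Volume(sim_grid, np.ones(sim_grid.shape), "kBq/mL")
        with pytest.raises(ValueError, match="counts"):
            nq.counts_to_concentration(img, nq.quantitative_factor(1, 1, 1))

    def test_calibration_round_trip_recovers_truth(self):
        # simulate a uniform cylinder, reconstruct to convergence with a
        # matched model, apply QF: the filled concentration comes back
        fill = nq.PhantomFill("99mTc", 40.0, 40.0)
        contour = nq.BodyContour(mode="elliptical", width=150.0, height=150.0,
                                 axial_extent=120.0)
        spec = nq.PhantomSpec((), contour, fill)
        grid = nq.VoxelGrid((12, 48, 48), (4.8, 4.8, 4.8))
        prot = nq.ScanProtocol(detector_fwhm_mm=0.0)
        vol = nq.voxelize(spec, grid, supersample=2)
        sino = nq.forward_project(vol, prot, grid)
        recon = nq.osem_reconstruct(
            sino, prot, nq.ReconSettings(iterations=20, subsets=4,
                                         post_filter_fwhm_mm=0), grid)
        conc = nq.counts_to_concentration(recon, nq.qf_for(prot, grid))
        interior = nq.background_mask(spec, grid, edge_margin=15.0)
        interior[:3] = interior[-3:] = False
        assert conc.mean_over(interior) == pytest.approx(40.0, rel=0.01)


class TestRecovery:
    def test_identity_on_truth(self, cold_spec, fine_cold_truth):
        # within the rasterization tolerance of the voxel-centre mask
        # rule: edge voxels bias the mean low by ~0.34 x spacing/radius
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        for r in nq.recovery_coefficients(fine_cold_truth, masks, cold_spec):
            assert r.rc == pytest.approx(1.0, rel=0.5 * 2.0 / r.diameter_mm)

    def test_results_ordered_by_descending_diameter(self, cold_spec, fine_cold_truth):
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        rcs = nq.recovery_coefficients(fine_cold_truth, masks, cold_spec)
        assert [r.diameter_mm for r in rcs] == [37.0, 28.0, 22.0, 17.0, 13.0, 10.0]

    def test_linearity(self, cold_spec, fine_cold_truth):
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        full = nq.recovery_coefficients(fine_cold_truth, masks, cold_spec)
        half = nq.recovery_coefficients(
            fine_cold_truth.with_values(fine_cold_truth.values / 2), masks, cold_spec)
        for a, b in zip(full, half):
            assert b.rc == pytest.approx(a.rc / 2)

    def test_blurred_matches_analytic_oracle(self, cold_spec, fine_cold_truth):
        blurred = nq.blur_model(fine_cold_truth, 8.4)
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        for r in nq.recovery_coefficients(blurred, masks, cold_spec):
            assert r.rc == pytest.approx(sphere_gauss_mean(r.diameter_mm, 8.4),
                                         rel=0.02)

    def test_decay_correction_option(self, cold_spec, fine_cold_truth):
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        plain = nq.recovery_coefficients(fine_cold_truth, masks, cold_spec)
        # truth decays for 6.01 h (one 99mTc half-life) before the scan
        corrected = nq.recovery_coefficients(fine_cold_truth, masks, cold_spec,
                                             decay_to_scan_h=6.01)
        for a, b in zip(plain, corrected):
            assert b.rc == pytest.approx(2 * a.rc, rel=1e-6)

    def test_requires_concentration_units(self, cold_spec, sim_grid):
        img = nq.Volume(sim_grid, np.ones(sim_grid.shape), "counts")
        masks = nq.sphere_masks(cold_spec, sim_grid)
        with pytest.raises(ValueError, match="kBq/mL"):
            nq.recovery_coefficients(img, masks, cold_spec)


class TestContrast:
    def test_identity_on_truth(self, warm_spec, fine_warm_truth):
        masks = nq.sphere_masks(warm_spec, fine_warm_truth.grid)
        bg = nq.background_mask(warm_spec, fine_warm_truth.grid)
        for c in nq.contrast(fine_warm_truth, masks, bg, warm_spec):
            # warm fill dilutes the edge-voxel bias by (1 - 1/A)
            assert c.contrast == pytest.approx(1.0, rel=0.5 * 2.0 / c.diameter_mm)

    def test_sphere_at_background_level_scores_one_over_a(self, warm_spec, sim_grid):
        # guards against the NU2 background-subtracted form: equal means
        # must give C = 1/A, not 0
        img = nq.Volume(sim_grid, np.ones(sim_grid.shape), "kBq/mL")
        masks = nq.sphere_masks(warm_spec, sim_grid)
        bg = nq.background_mask(warm_spec, sim_grid)
        a = warm_spec.fill.true_ratio
        for c in nq.contrast(img, masks, bg, warm_spec):
            assert c.contrast == pytest.approx(1.0 / a)
            assert c.nu2_percent_contrast == pytest.approx(0.0, abs=1e-12)

    def test_half_ratio_gives_half_contrast(self, warm_spec, sim_grid):
        a = warm_spec.fill.true_ratio
        vals = np.ones(sim_grid.shape)
        masks = nq.sphere_masks(warm_spec, sim_grid)
        for m in masks:
            vals[m] = a / 2.0
        img = nq.Volume(sim_grid, vals, "kBq/mL")
        bg = nq.background_mask(warm_spec, sim_grid)
        for c in nq.contrast(img, masks, bg, warm_spec):
            assert c.contrast == pytest.approx(0.5)

    def test_invariant_to_global_rescale_and_unit(self, warm_spec, fine_warm_truth):
        masks = nq.sphere_masks(warm_spec, fine_warm_truth.grid)
        bg = nq.background_mask(warm_spec, fine_warm_truth.grid)
        base = nq.contrast(fine_warm_truth, masks, bg, warm_spec)
        as_counts = nq.Volume(fine_warm_truth.grid, fine_warm_truth.values * 37.5,
                              "counts")
        scaled = nq.contrast(as_counts, masks, bg, warm_spec)
        for a, b in zip(base, scaled):
            assert b.contrast == pytest.approx(a.contrast, rel=1e-12)

    def test_monotone_in_diameter_under_blur(self, warm_spec, fine_warm_truth):
        blurred = nq.blur_model(fine_warm_truth, 10.0)
        masks = nq.sphere_masks(warm_spec, blurred.grid)
        bg = nq.background_mask(warm_spec, blurred.grid)
        cs = nq.contrast(blurred, masks, bg, warm_spec)  # descending diameter
        values = [c.contrast for c in cs]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[0] > values[-1]  # smallest sphere well below largest

    def test_cold_background_rejected(self, cold_spec, fine_cold_truth):
        masks = nq.sphere_masks(cold_spec, fine_cold_truth.grid)
        bg = nq.background_mask(cold_spec, fine_cold_truth.grid)
        with pytest.raises(ValueError, match="cold"):
            nq.contrast(fine_cold_truth, masks, bg, cold_spec)


class TestIterationSweep:
    def test_table_shape_and_keys(self, noise_free_sweep):
        assert len(noise_free_sweep) == 36  # 6 settings x 6 spheres
        assert set(noise_free_sweep["iterations"]) == {1, 2, 4, 8, 16, 32}
        assert set(noise_free_sweep["diameter_mm"]) == {37, 28, 22, 17, 13, 10}
        for col in ("rc", "contrast", "background_cv", "isotope", "modality"):
            assert col in noise_free_sweep.columns
        assert noise_free_sweep["contrast"].notna().all()

    def test_empty_iteration_list_rejected(self, warm_spec, sim_grid,
                                           spect_protocol):
        with pytest.raises(ValueError, match="non-empty"):
            nq.iteration_sweep(warm_spec, spect_protocol, sim_grid,
                               iterations_list=())

    def test_contrast_nan_for_cold_fill(self, cold_spec, tiny_grid,
                                        suppress_geometry_warnings):
        df = nq.iteration_sweep(cold_spec, nq.ScanProtocol(), tiny_grid,
                                seed=None, iterations_list=(1,))
        assert df["contrast"].isna().all()
        assert df["rc"].notna().all()
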