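"""MBLL inversion, correction factors, ROI statistics, theoretical deltas."""

import numpy as np
import pytest

from cortexhsi import spectra as sp
from cortexhsi import unmixing as um
from cortexhsi.imaging import DetectorConfig
from cortexhsi.phantom import VesselMask
from cortexhsi.studies import OPTIMAL_8_WAVELENGTHS

from conftest import make_cube

WL8 = np.array(OPTIMAL_8_WAVELENGTHS)
WL25 = np.arange(780.0, 901.0, 5.0)
WL121 = np.arange(780.0, 901.0, 1.0)


class TestAttenuationChange:
    def test_equal_cubes_zero(self):
        base = make_cube(WL8, 2.0)
        assert np.allclose(um.attenuation_change(base, base).delta_A, 0.0)

    def test_decadic_unit(self):
        base = make_cube(WL8, 1.0)
        hyp = make_cube(WL8, 0.1)
        assert np.allclose(um.attenuation_change(base, hyp).delta_A, 1.0)

    def test_brightening_negative(self):
        base = make_cube(WL8, 1.0)
        hyp = make_cube(WL8, 2.0)
        assert np.allclose(um.attenuation_change(base, hyp).delta_A,
                           -np.log10(2.0))

    def test_empty_pixels_missing(self):
        inten = np.ones((8, 4, 4))
        inten[:, 0, 0] = 0.0
        base = make_cube(WL8, inten)
        hyp = make_cube(WL8, 1.0)
        dA = um.attenuation_change(base, hyp).delta_A
        assert np.isnan(dA[:, 0, 0]).all()
        assert np.isfinite(dA[:, 1, 1]).all()

    def test_mismatched_cubes_rejected(self):
        with pytest.raises(ValueError):
            um.attenuation_change(make_cube(WL8, 1.0), make_cube(WL25, 1.0))


class TestMeanPathlength:
    def test_identity_and_mean(self):
        a = make_cube(WL8, 1.0, pl_total=2.0)
        b = make_cube(WL8, 1.0, pl_total=4.0)
        assert np.allclose(um.mean_pathlength(a, a), 2.0)
        assert np.allclose(um.mean_pathlength(a, b), 3.0)

    def test_missing_propagates(self):
        plt = np.full((8, 4, 4), 2.0)
        plt[:, 1, 1] = np.nan
        a = make_cube(WL8, 1.0, pl_total=plt)
        b = make_cube(WL8, 1.0, pl_total=2.0)
        mean = um.mean_pathlength(a, b)
        assert np.isnan(mean[:, 1, 1]).all()
        assert np.isfinite(mean[:, 0, 0]).all()


class TestSolveMBLL:
    @pytest.mark.parametrize("wl", [WL121, WL25, WL8], ids=["121", "25", "8"])
    def test_forward_round_trip(self, spectra, wl):
        # forward-synthesized attenuation from known deltas inverts exactly
        rng = np.random.default_rng(3)
        pl = rng.uniform(0.5, 6.0, size=(len(wl), 5, 5))
        truth = (-17.44, 43.60, -3.0)
        dA = um.synthesize_attenuation(*truth, pathlength=pl, spectra=spectra,
                                       wavelengths=wl)
        maps = um.solve_mbll(dA, pl, spectra)
        assert np.allclose(maps.dhbo2, truth[0], atol=1e-8)
        assert np.allclose(maps.dhhb, truth[1], atol=1e-8)
        assert np.allclose(maps.doxcco, truth[2], atol=1e-8)

    def test_zero_attenuation_zero_deltas(self, spectra):
        pl = np.full((8, 3, 3), 5.0)
        dA = um.AttenuationCube(np.zeros((8, 3, 3)), WL8)
        maps = um.solve_mbll(dA, pl, spectra)
        for arr in (maps.dhbo2, maps.dhhb, maps.doxcco):
            assert np.allclose(arr, 0.0, atol=1e-12)

    def test_single_chromophore_no_crosstalk(self, spectra):
        pl = np.full((8, 2, 2), 5.0)
        dA = um.synthesize_attenuation(0.0, 100.0, 0.0, pathlength=pl,
                                       spectra=spectra, wavelengths=WL8)
        maps = um.solve_mbll(dA, pl, spectra)
        assert np.allclose(maps.dhhb, 100.0, atol=1e-8)
        assert np.allclose(maps.dhbo2, 0.0, atol=1e-8)
        assert np.allclose(maps.doxcco, 0.0, atol=1e-8)

    def test_duplicate_wavelengths_rejected(self, spectra):
        wl = np.array([835.0, 835.0, 835.0])
        pl = np.full((3, 2, 2), 5.0)
        dA = um.AttenuationCube(np.zeros((3, 2, 2)), wl)
        with pytest.raises(ValueError, match="condition number"):
            um.solve_mbll(dA, pl, spectra)

    def test_too_few_wavelengths_rejected(self, spectra):
        dA = um.AttenuationCube(np.zeros((2, 2, 2)), np.array([800.0, 850.0]))
        with pytest.raises(ValueError, match="3 wavelengths"):
            um.solve_mbll(dA, np.ones((2, 2, 2)), spectra)

    def test_missing_pixels_stay_missing(self, spectra):
        pl = np.full((8, 2, 2), 5.0)
        dA = um.synthesize_attenuation(1.0, 2.0, 3.0, pathlength=pl,
                                       spectra=spectra, wavelengths=WL8)
        dA.delta_A[2, 0, 0] = np.nan
        maps = um.solve_mbll(dA, pl, spectra)
        assert np.isnan(maps.dhbo2[0, 0])
        assert np.isfinite(maps.dhbo2[1, 1])


class TestCorrectionFactors:
    def test_full_vessel_path_unity(self):
        cube = make_cube(WL8, 1.0, pl_total=2.0, pl_vessel=2.0)
        cf = um.correction_factors(cube, cube)
        assert np.allclose(cf.cf_vessel, 1.0)

    def test_half_vessel_path_doubles(self):
        cube = make_cube(WL8, 1.0, pl_total=2.0, pl_vessel=1.0)
        cf = um.correction_factors(cube, cube)
        assert np.allclose(cf.cf_vessel, 2.0)
        assert np.allclose(cf.cf_gray, 2.0)

    def test_cross_condition_mean(self):
        a = make_cube(WL8, 1.0, pl_total=2.0, pl_vessel=1.0)   # ratio 2
        b = make_cube(WL8, 1.0, pl_total=4.0, pl_vessel=1.0)   # ratio 4
        cf = um.correction_factors(a, b)
        assert np.allclose(cf.cf_vessel, 3.0)

    def test_zero_denominator_missing(self):
        cube = make_cube(WL8, 1.0, pl_total=2.0, pl_vessel=0.0)
        cf = um.correction_factors(cube, cube)
        assert np.isnan(cf.cf_vessel).all()
        assert np.isfinite(cf.cf_gray).all()


class TestApplyCorrection:
    def _maps(self, value=10.0, shape=(4, 4)):
        return um.ConcentrationMaps(np.full(shape, -value),
                                    np.full(shape, 2 * value),
                                    np.full(shape, -3.0))

    def _cf(self, cfv, cfg, shape=(4, 4)):
        return um.CorrectionMaps(np.full(shape, float(cfv)),
                                 np.full(shape, float(cfg)), 8)

    def test_unit_factors_are_identity(self):
        maps = self._maps()
        out = um.apply_correction(maps, self._cf(1.0, 1.0),
                                  np.zeros((4, 4), dtype=bool))
        assert np.allclose(out.dhbo2, maps.dhbo2)
        assert np.allclose(out.doxcco, maps.doxcco)

    def test_vessel_pixels_scale_hemoglobin_only(self):
        # the published example ratio: -32.89 uM with CF' = 14.43 restores
        # the order of the theoretical -465 uM vascular change
        maps = um.ConcentrationMaps(np.full((2, 2), -32.89),
                                    np.full((2, 2), 82.78),
                                    np.full((2, 2), -2.929))
        vessel = np.ones((2, 2), dtype=bool)
        out = um.apply_correction(maps, self._cf(14.43, 1.0, (2, 2)), vessel)
        assert out.dhbo2[0, 0] == pytest.approx(-474.6, abs=0.5)
        assert out.dhhb[0, 0] == pytest.approx(82.78 * 14.43, rel=1e-12)
        assert out.doxcco[0, 0] == pytest.approx(-2.929)  # metabolic untouched

    def test_gray_pixels_scale_all_three(self):
        maps = self._maps()
        out = um.apply_correction(maps, self._cf(5.0, 1.1),
                                  np.zeros((4, 4), dtype=bool))
        assert np.allclose(out.dhbo2, maps.dhbo2 * 1.1)
        assert np.allclose(out.dhhb, maps.dhhb * 1.1)
        assert np.allclose(out.doxcco, maps.doxcco * 1.1)

    def test_undefined_cf_passes_through_flagged(self):
        maps = self._maps()
        cf = self._cf(np.nan, 1.0)
        vessel = np.ones((4, 4), dtype=bool)
        out = um.apply_correction(maps, cf, vessel)
        assert np.allclose(out.dhbo2, maps.dhbo2)
        assert out.n_uncorrectable == 16

    def test_unregistered_mask_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            um.apply_correction(self._maps(), self._cf(1.0, 1.0),
                                np.zeros((3, 3), dtype=bool))


class TestMaskRegistration:
    def test_majority_vote_and_tie(self):
        px = np.zeros((10, 10), dtype=bool)
        px[:, :5] = True            # left half vessel
        mask = VesselMask(px, 0.12)  # 1.2 mm across at 10 px
        det = DetectorConfig(fov_size=(1.2, 1.2), n_pixels=(5, 5))
        grid = um.mask_to_pixel_grid(mask, det)
        assert grid[:, :2].all()
        assert not grid[:, 3:].any()
        # column 2 of 5 covers mask columns 4-5: one vessel, one not: tie
        assert grid[:, 2].all()

    def test_fraction_preserved(self, default_phantom):
        det = DetectorConfig()
        grid = um.mask_to_pixel_grid(default_phantom.mask, det)
        assert grid.mean() == pytest.approx(default_phantom.mask.vessel_fraction,
                                            abs=0.03)


class TestROIs:
    def test_constant_map(self):
        st = um.roi_stats(np.full((20, 20), 7.0), um.ROISpec(5, 5, 10))
        assert st.mean == 7.0 and st.std == 0.0 and st.n_missing == 0

    def test_half_and_half(self):
        m = np.zeros((20, 20))
        m[:, :] = 2.0
        m[10:, :] = 4.0
        st = um.roi_stats(m, um.ROISpec(5, 5, 10))
        assert st.mean == pytest.approx(3.0)

    def test_partially_missing(self):
        m = np.full((20, 20), 5.0)
        m[5:8, 5:15] = np.nan
        st = um.roi_stats(m, um.ROISpec(5, 5, 10))
        assert st.mean == 5.0
        assert st.n_missing == 30

    def test_out_of_bounds_and_all_missing(self):
        with pytest.raises(ValueError, match="bounds"):
            um.roi_stats(np.zeros((5, 5)), um.ROISpec(0, 0, 10))
        with pytest.raises(ValueError, match="no valid"):
            um.roi_stats(np.full((20, 20), np.nan), um.ROISpec(0, 0, 10))

    def test_default_rois_land_in_their_phase(self, default_phantom):
        det = DetectorConfig(n_pixels=(37, 37))
        grid = um.mask_to_pixel_grid(default_phantom.mask, det)
        rois = um.default_rois(grid, size=2)
        assert grid[rois["vasculature"].slices()].all()
        assert not grid[rois["gray_matter"].slices()].any()


class TestTheoreticalDeltas:
    def test_vasculature_pair(self):
        d = um.theoretical_deltas(sp.VASCULATURE_BASELINE, sp.VASCULATURE_HYPOXIA)
        assert d[0] == pytest.approx(-465.12, abs=0.05)
        assert d[1] == pytest.approx(1162.79, abs=0.05)
        assert d[2] == 0.0

    def test_gray_matter_pair(self):
        d = um.theoretical_deltas(sp.GRAY_MATTER_BASELINE, sp.GRAY_MATTER_HYPOXIA)
        assert d[0] == pytest.approx(-17.44, abs=0.05)
        assert d[1] == pytest.approx(43.60, abs=0.05)
        assert d[2] == pytest.approx(-3.0, abs=1e-12)

    def test_identical_compositions_zero(self):
        d = um.theoretical_deltas(sp.GRAY_MATTER_BASELINE, sp.GRAY_MATTER_BASELINE)
        assert d == (0.0, 0.0, 0.0)
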