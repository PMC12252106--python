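import numpy as np
import pytest

from ramanmix.cube import BandWindow, CubeError, HyperCube, PixelMask, SpectralAxis, Spectrum
from ramanmix.postanalysis import (
    average_spectrum,
    exclusive_masks,
    group_test,
    normalize_subtract,
    resolution,
    snr_map,
)
from ramanmix.segmentation import ThresholdSpec
from ramanmix.unmixing import AbundanceStack


def stack_from_maps(maps):
    maps = np.asarray(maps, dtype=float)
    h, w, _ = maps.shape
    return AbundanceStack(
        maps=maps,
        endmembers=None,
        method="nnls",
        mask=PixelMask(np.ones((h, w), dtype=bool), ["all"]),
    )


class TestExclusiveMasks:
    def test_hand_evaluated_overlap_removal(self):
        a = np.array([[1.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        stack = stack_from_maps(np.dstack([a, b]))
        masks = exclusive_masks(stack, ThresholdSpec("absolute", 0.5))
        # pixel (x=0, y=1) is strong in both maps -> removed from both
        assert masks[0].flags.tolist() == [[True, False], [False, True]]
        assert masks[1].flags.tolist() == [[False, True], [False, False]]

    def test_single_map_unchanged_by_intersection(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        masks = exclusive_masks(stack_from_maps(a[:, :, None]), ThresholdSpec("absolute", 0.5))
        assert masks[0].flags.tolist() == [[True, False], [False, True]]

    def test_identical_maps_empty_with_warning(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        stack = stack_from_maps(np.dstack([a, a]))
        with pytest.warns(UserWarning, match="emptied"):
            masks = exclusive_masks(stack, ThresholdSpec("absolute", 0.5))
        assert not masks[0].flags.any()
        assert not masks[1].flags.any()

    def test_outputs_pairwise_disjoint(self):
        rng = np.random.default_rng(0)
        stack = stack_from_maps(rng.random((10, 10, 3)))
        masks = exclusive_masks(stack)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (masks[i].flags & masks[j].flags).any()


class TestAverageSpectrum:
    def make_cube(self, rows):
        rows = np.asarray(rows, dtype=float)
        data = rows.reshape(1, rows.shape[0], rows.shape[1])
        return HyperCube(data, SpectralAxis(np.arange(rows.shape[1], dtype=float) + 1))

    def test_arithmetic_mean(self):
        cube = self.make_cube([[1.0, 3.0], [3.0, 5.0]])
        mask = PixelMask(np.array([[True, True]]), ["m"])
        res = average_spectrum(cube, mask)
        assert np.allclose(res.spectrum.intensities, [2.0, 4.0])
        assert res.n_pixels == 2

    def test_single_pixel(self):
        cube = self.make_cube([[1.0, 3.0], [3.0, 5.0]])
        mask = PixelMask(np.array([[False, True]]), ["m"])
        assert np.allclose(average_spectrum(cube, mask).spectrum.intensities, [3.0, 5.0])

    def test_linearity_in_cube(self):
        rng = np.random.default_rng(1)
        rows = rng.random((4, 5))
        mask = PixelMask(np.array([[True, False, True, True]]), ["m"])
        a = average_spectrum(self.make_cube(rows), mask).spectrum.intensities
        b = average_spectrum(self.make_cube(2 * rows), mask).spectrum.intensities
        assert np.allclose(b, 2 * a)

    def test_empty_mask_errors(self):
        cube = self.make_cube([[1.0, 2.0]])
        with pytest.raises(CubeError, match="non-empty"):
            average_spectrum(cube, PixelMask(np.array([[False]]), ["m"]))


class TestNormalizeSubtract:
    axis = SpectralAxis(np.arange(100.0, 200.0))

    def peak(self, c, h=1.0, fwhm=10.0):
        wn = self.axis.wavenumbers
        return h * np.exp(-4 * np.log(2) * ((wn - c) / fwhm) ** 2)

    def test_identical_spectra_zero_difference(self):
        s = Spectrum(self.axis, self.peak(150) + 0.1)
        d = normalize_subtract(s, s, baseline_params=None)
        assert np.allclose(d.intensities, 0.0, atol=1e-12)

    def test_normalization_contract(self):
        a = Spectrum(self.axis, self.peak(150, 2.0))
        r = Spectrum(self.axis, self.peak(150, 5.0))
        w = BandWindow(140, 160)
        # each normalized spectrum has max 1 inside the window
        d = normalize_subtract(a, r, window=w, baseline_params=None)
        assert np.allclose(d.intensities, 0.0, atol=1e-9)

    def test_minority_band_survives_subtraction(self):
        matrix = self.peak(150)
        mixed = 0.95 * matrix + 0.05 * self.peak(170)
        d = normalize_subtract(
            Spectrum(self.axis, mixed), Spectrum(self.axis, matrix), baseline_params=None
        )
        peak_at = self.axis.wavenumbers[np.argmax(d.intensities)]
        assert abs(peak_at - 170) <= 2

    def test_reference_resampled_when_axes_differ(self):
        ref_axis = SpectralAxis(np.arange(100.0, 200.0, 2.0))
        wn = ref_axis.wavenumbers
        ref = Spectrum(ref_axis, np.exp(-4 * np.log(2) * ((wn - 150) / 25) ** 2))
        avg = Spectrum(self.axis, self.peak(150, fwhm=25.0))
        d = normalize_subtract(avg, ref, baseline_params=None)
        # residual bounded by the linear-interpolation error of the profile
        assert np.abs(d.intensities).max() < 0.01

    def test_zero_max_errors(self):
        z = Spectrum(self.axis, np.zeros(100))
        with pytest.raises(CubeError):
            normalize_subtract(z, z, baseline_params=None)


class TestSnrMap:
    def test_center_pixel_hand_computed(self):
        """3x3 image with S = 1..9: center SNR = 5 / population std."""
        s = np.arange(1.0, 10.0).reshape(3, 3)
        data = s[:, :, None] * np.array([1.0, 0.5])[None, None, :]
        cube = HyperCube(data, SpectralAxis(np.array([1.0, 2.0])))
        res = snr_map(cube)
        expected = 5.0 / np.std(np.arange(1.0, 10.0))  # ddof=0
        assert res.values[1, 1] == pytest.approx(expected)
        assert res.s_map[1, 1] == 5.0

    def test_constant_s_is_undefined_everywhere(self):
        data = np.full((4, 4, 3), 2.0)
        cube = HyperCube(data, SpectralAxis(np.array([1.0, 2.0, 3.0])))
        res = snr_map(cube)
        assert res.undefined_mask.all()
        assert np.all(res.values == 0)

    def test_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(2)
        data = rng.random((5, 5, 4))
        ax = SpectralAxis(np.arange(4.0) + 1)
        a = snr_map(HyperCube(data, ax))
        b = snr_map(HyperCube(3.7 * data, ax))
        assert np.allclose(a.values, b.values)

    def test_quantifiability_threshold_classification(self):
        """Pixels below SNR 2 are the non-quantifiable set."""
        rng = np.random.default_rng(3)
        data = rng.random((6, 6, 3))
        res = snr_map(HyperCube(data, SpectralAxis(np.arange(3.0) + 1)))
        not_quantifiable = (res.values < 2.0) & ~res.undefined_mask
        assert not_quantifiable.shape == (6, 6)
        assert ((res.values[~res.undefined_mask] < 2.0) == not_quantifiable[~res.undefined_mask]).all()


class TestResolution:
    def test_formulas_to_machine_precision(self):
        r = resolution(532.0, 0.75)
        assert r.dx_nm == pytest.approx(0.61 * 532 / 0.75, rel=1e-15)
        assert r.dz_nm == pytest.approx(0.89 * 532 / 0.75**2, rel=1e-15)

    def test_printed_values_na_075(self):
        r = resolution(532.0, 0.75)
        assert round(r.dx_nm) == 433
        assert round(r.dz_nm) == 842

    def test_printed_values_na_04(self):
        r = resolution(532.0, 0.4)
        assert round(r.dx_nm) == 811
        assert round(r.dz_nm) == 2959

    def test_na_scaling(self):
        r1, r2 = resolution(532, 0.4), resolution(532, 0.8)
        assert r2.dx_nm == pytest.approx(r1.dx_nm / 2)
        assert r2.dz_nm == pytest.approx(r1.dz_nm / 4)

    def test_invalid_inputs(self):
        with pytest.raises(CubeError):
            resolution(-1, 0.5)
        with pytest.raises(CubeError):
            resolution(532, 0.0)


class TestGroupTest:
    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        rep = group_test(a, b)
        assert rep.significant
        assert rep.mannwhitney_p < 1e-6

    def test_reports_all_statistics(self):
        rng = np.random.default_rng(1)
        rep = group_test(rng.normal(size=20), rng.normal(size=25), alpha=0.01)
        assert 0 <= rep.shapiro_p[0] <= 1
        assert 0 <= rep.levene_p <= 1
        assert rep.alpha == 0.01

    def test_small_group_errors(self):
        with pytest.raises(CubeError, match="n >= 3"):
            group_test([1.0, 2.0], [1.0, 2.0, 3.0])
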