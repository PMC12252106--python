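import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramanmix.cube import BandWindow, CubeError, HyperCube, IntensityMap, PixelMask, SpectralAxis
from ramanmix.segmentation import (
    MorphSpec,
    ThresholdSpec,
    band_intensity_map,
    binarize,
    build_segmented_spectra,
    mask_fraction,
    merge_masks,
    morph_clean,
    segment_cube,
)


def cube_from_planes(values, wavenumbers):
    """Single-pixel cube with the given per-channel values."""
    values = np.asarray(values, dtype=float)
    data = values.reshape(1, 1, -1)
    return HyperCube(data, SpectralAxis(np.asarray(wavenumbers, dtype=float)))


class TestBandIntensityMap:
    def test_max_statistic(self):
        cube = cube_from_planes([1.0, 5.0, 2.0], [950, 959, 970])
        m = band_intensity_map(cube, BandWindow(950, 970), "max")
        assert m.values[0, 0] == 5.0

    def test_sum_statistic(self):
        cube = cube_from_planes([1.0, 2.0, 3.0], [950, 959, 970])
        m = band_intensity_map(cube, BandWindow(950, 970), "sum")
        assert m.values[0, 0] == 6.0

    def test_empty_overlap_errors(self):
        cube = cube_from_planes([1.0, 2.0], [100, 200])
        with pytest.raises(CubeError):
            band_intensity_map(cube, BandWindow(900, 950))


class TestBinarize:
    def test_percentile_median(self):
        m = IntensityMap(np.array([[1.0, 2.0], [3.0, 4.0]]), BandWindow(0, 1))
        mask = binarize(m, ThresholdSpec("percentile", 50))
        assert mask.flags.tolist() == [[False, False], [True, True]]
        assert any("binarize" in p for p in mask.provenance)

    def test_absolute_zero_on_positive_map(self):
        m = IntensityMap(np.full((3, 3), 0.5), BandWindow(0, 1))
        mask = binarize(m, ThresholdSpec("absolute", 0.0))
        assert mask.flags.all()

    def test_otsu_matches_exhaustive_search(self):
        """Otsu boundary agrees with brute-force inter-class-variance max."""
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(1, 0.2, 600), rng.normal(10, 1.0, 400)])
        m = IntensityMap(vals.reshape(20, 50), BandWindow(0, 1))
        mask = binarize(m, ThresholdSpec("otsu"))
        # brute force over candidate thresholds
        cands = np.sort(vals)
        best_t, best_v = None, -1.0
        for t in cands[:-1]:
            lo, hi = vals[vals <= t], vals[vals > t]
            v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        expected = m.values > best_t
        assert (mask.flags == expected).mean() > 0.995

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_threshold(self, p_low, p_high):
        """Raising the threshold never adds pixels."""
        p_low, p_high = sorted([p_low, p_high])
        rng = np.random.default_rng(9)
        m = IntensityMap(rng.random((6, 6)), BandWindow(0, 1))
        lo = binarize(m, ThresholdSpec("percentile", p_low)).flags
        hi = binarize(m, ThresholdSpec("percentile", p_high)).flags
        assert not (hi & ~lo).any()


class TestMorphology:
    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(0)
        mask = PixelMask(rng.random((8, 8)) > 0.5, ["seed"])
        out = morph_clean(mask, MorphSpec(("erode", "dilate"), 1))
        assert np.array_equal(out.flags, mask.flags)

    def test_opening_removes_isolated_pixel(self):
        flags = np.zeros((9, 9), dtype=bool)
        flags[4, 4] = True
        out = morph_clean(PixelMask(flags, ["seed"]), MorphSpec(("erode", "dilate"), 3))
        assert not out.flags.any()

    def test_opening_preserves_solid_block(self):
        flags = np.zeros((11, 11), dtype=bool)
        flags[3:8, 3:8] = True
        out = morph_clean(PixelMask(flags, ["seed"]), MorphSpec(("erode", "dilate"), 3))
        assert np.array_equal(out.flags, flags)


class TestMergeMasks:
    def test_union(self):
        a = PixelMask(np.array([[True, False]]), ["a"])
        b = PixelMask(np.array([[False, False]]), ["b"])
        assert merge_masks([a, b]).flags.tolist() == [[True, False]]

    def test_idempotent(self):
        a = PixelMask(np.array([[True, False], [False, True]]), ["a"])
        assert np.array_equal(merge_masks([a, a]).flags, a.flags)

    def test_disjoint_thirds_cover_all(self):
        masks = []
        for i in range(3):
            f = np.zeros((3, 3), dtype=bool)
            f[i, :] = True
            masks.append(PixelMask(f, [f"m{i}"]))
        assert merge_masks(masks).flags.all()

    def test_shape_mismatch_errors(self):
        a = PixelMask(np.zeros((2, 2), dtype=bool), ["a"])
        b = PixelMask(np.zeros((3, 2), dtype=bool), ["b"])
        with pytest.raises(CubeError, match="shape"):
            merge_masks([a, b])


class TestSegmentedSpectra:
    def make(self):
        ax = SpectralAxis(np.array([1000.0, 1500.0, 2900.0, 2950.0]))
        data = np.arange(2 * 2 * 4, dtype=float).reshape(2, 2, 4)
        cube = HyperCube(data, ax)
        mask = PixelMask(np.array([[True, False], [True, True]]), ["seed"])
        return cube, mask

    def test_fill_value_outside_windows(self):
        cube, mask = self.make()
        seg = build_segmented_spectra(cube, [BandWindow(2800, 3000)], mask)
        assert (seg.data[:, :, 0] == 1.0).all()  # 1000 cm-1 outside
        assert (seg.data[:, :, 1] == 1.0).all()  # 1500 cm-1 outside

    def test_copy_inside_window(self):
        cube, mask = self.make()
        seg = build_segmented_spectra(cube, [BandWindow(2800, 3000)], mask)
        assert np.array_equal(seg.data[:, :, 2:], cube.data[:, :, 2:])

    def test_overlapping_windows_union(self):
        cube, mask = self.make()
        seg = build_segmented_spectra(
            cube, [BandWindow(2800, 2920), BandWindow(2890, 3000)], mask
        )
        assert np.array_equal(seg.data[:, :, 2:], cube.data[:, :, 2:])
        assert (seg.data[:, :, :2] == 1.0).all()

    def test_invariant_holds_channelwise(self):
        cube, mask = self.make()
        seg = build_segmented_spectra(cube, [BandWindow(2800, 3000)], mask, fill_value=0.0)
        outside = np.setdiff1d(np.arange(4), seg.window_channels)
        assert (seg.data[:, :, outside] == 0.0).all()

    def test_no_overlap_errors(self):
        cube, mask = self.make()
        with pytest.raises(CubeError):
            build_segmented_spectra(cube, [BandWindow(100, 200)], mask)


class TestPhantomSegmentation:
    def lines_scene(self, coverage=0.15, noise=0.01, seed=0):
        from ramanmix.synthcube import BandSpec, ComponentSpec, SceneSpec

        return SceneSpec(
            components={
                "A": ComponentSpec((BandSpec(2935, 30, 1.0),), 0.9),
                "B": ComponentSpec((BandSpec(959, 14, 1.0),), 0.1),
            },
            matrix="A",
            minority="B",
            fiber_pattern="lines",
            fiber_coverage=coverage,
            noise_sigma=noise,
            baseline_spatial_jitter=0.0 if noise == 0 else 0.2,
            spike_count=0,
            segmentation_windows=(BandWindow(2800, 3050),),
            seed=seed,
        )

    def test_fraction_matches_fiber_coverage(self):
        """Default segmentation recovers a 15%-coverage scene within 2 pp."""
        from ramanmix.synthcube import make_phantom
        from ramanmix.preprocess import preprocess_cube, DrplsParams

        cube, truth = make_phantom(self.lines_scene())
        proc, _ = preprocess_cube(cube, None, None, DrplsParams())
        mask, _ = segment_cube(proc, [BandWindow(2800, 3050)])
        assert abs(mask_fraction(mask) - 0.15) <= 0.02

    def test_noise_free_scene_recovered_cleanly(self):
        """>=98% of fiber pixels kept, <=2% false positives, no noise."""
        from ramanmix.synthcube import make_phantom
        from ramanmix.preprocess import preprocess_cube, DrplsParams

        cube, truth = make_phantom(self.lines_scene(noise=0.0, seed=2))
        proc, _ = preprocess_cube(cube, None, None, DrplsParams())
        # one discriminating band per compound, masks merged
        mask, _ = segment_cube(proc, [BandWindow(2800, 3050), BandWindow(930, 990)])
        fiber = truth.fiber_mask
        tp = (mask.flags & fiber).sum() / fiber.sum()
        fp = (mask.flags & ~fiber).sum() / max(1, mask.flags.sum())
        assert tp >= 0.98
        assert fp <= 0.02
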