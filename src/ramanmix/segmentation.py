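"""Pixel and band segmentation for hyperspectral Raman images.

The workflow builds one intensity map per discriminating band of each
compound, binarizes each map with a threshold, cleans the binary image
morphologically, and merges the per-band masks (sum, then binarize again)
into the set of pixels carrying chemical information.  The retained band
windows of the processed cube are spliced into "synthetic spectra" that
equal the processed data inside the windows and a constant fill value
(default 1) outside, which is the representation the endmember extraction
operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, erosion

from .cube import BandWindow, CubeError, HyperCube, IntensityMap, PixelMask

__all__ = [
    "ThresholdSpec",
    "MorphSpec",
    "SegmentedCube",
    "band_intensity_map",
    "resolve_threshold",
    "binarize",
    "morph_clean",
    "merge_masks",
    "build_segmented_spectra",
    "mask_fraction",
    "segment_cube",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold rule: absolute level, percentile of the map, or Otsu."""

    method: str = "percentile"
    value: float = 75.0

    def __post_init__(self) -> None:
        if self.method not in ("absolute", "percentile", "otsu"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "percentile" and not (0 <= self.value <= 100):
            raise ValueError(f"percentile value must be in [0, 100], got {self.value}")


@dataclass(frozen=True)
class MorphSpec:
    """Ordered erosion/dilation sequence with a square structuring element.

    A kernel of 1 is the identity (kept available because it is a common
    published choice); the default opening (erode then dilate, kernel 3)
    actually removes isolated anomalous pixels.
    """

    op_sequence: tuple[str, ...] = ("erode", "dilate")
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        for op in self.op_sequence:
            if op not in ("erode", "dilate"):
                raise ValueError(f"unknown morphological op {op!r}")


@dataclass
class SegmentedCube:
    """H×W×B synthetic spectra: processed data inside windows, fill outside."""

    data: np.ndarray
    axis: "np.ndarray | object"
    windows: list[BandWindow]
    fill_value: float
    mask: PixelMask
    window_channels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def masked_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, B) spectra of masked pixels and their (N, 2) (x, y) coordinates."""
        ys, xs = np.nonzero(self.mask.flags)
        flat = self.data[ys, xs, :]
        coords = np.column_stack([xs, ys])
        return flat, coords


def band_intensity_map(
    cube: HyperCube, band: BandWindow, stat: str = "max"
) -> IntensityMap:
    """Per-pixel max (default) or sum of intensity over a band window."""
    idx = cube.axis.window_indices(band)
    if idx.size == 0:
        raise CubeError(
            f"band window [{band.lo}, {band.hi}] does not overlap the cube axis"
        )
    sub = cube.data[:, :, idx]
    if stat == "max":
        values = sub.max(axis=2)
    elif stat == "sum":
        values = sub.sum(axis=2)
    else:
        raise CubeError(f"unknown band statistic {stat!r}; use 'max' or 'sum'")
    return IntensityMap(values, band)


def resolve_threshold(values: np.ndarray, spec: ThresholdSpec) -> float:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise CubeError("intensity map contains non-finite values")
    if spec.method == "absolute":
        return float(spec.value)
    if spec.method == "percentile":
        return float(np.percentile(values, spec.value))
    return float(threshold_otsu(values))


def binarize(intensity_map: IntensityMap, spec: ThresholdSpec) -> PixelMask:
    """Mask of pixels strictly above the resolved threshold."""
    thr = resolve_threshold(intensity_map.values, spec)
    flags = intensity_map.values > thr
    if not flags.any():
        warnings.warn("binarize produced an all-false mask", stacklevel=2)
    prov = f"binarize:method={spec.method}:threshold={thr:.10g}"
    return PixelMask(flags, [prov])


def morph_clean(mask: PixelMask, spec: MorphSpec = MorphSpec()) -> PixelMask:
    flags = mask.flags
    if spec.kernel > 1:
        footprint = np.ones((spec.kernel, spec.kernel), dtype=bool)
        for op in spec.op_sequence:
            if op == "erode":
                flags = erosion(flags, footprint)
            else:
                flags = dilation(flags, footprint)
    prov = f"morph:{'-'.join(spec.op_sequence)}:kernel={spec.kernel}"
    return PixelMask(flags, mask.provenance + [prov])


def merge_masks(masks: list[PixelMask]) -> PixelMask:
    """Union of masks (sum >= 1 then binarize); provenance concatenated."""
    if len(masks) == 0:
        raise CubeError("merge_masks requires at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise CubeError(f"mask shape mismatch: {m.shape} vs {shape}")
    total = np.zeros(shape, dtype=int)
    prov: list[str] = []
    for m in masks:
        total += m.flags.astype(int)
        prov.extend(m.provenance)
    return PixelMask(total >= 1, prov + [f"merge:n={len(masks)}"])


def build_segmented_spectra(
    cube: HyperCube,
    windows: list[BandWindow],
    mask: PixelMask,
    fill_value: float = 1.0,
) -> SegmentedCube:
    """Splice retained band windows into constant-fill synthetic spectra.

    Channels inside the union of windows copy the processed cube; all other
    channels carry ``fill_value`` (the published convention uses 1).
    Unmasked pixels are retained positionally so maps can be reconstructed,
    but downstream unmixing only consumes masked pixels.
    """
    if not windows:
        raise CubeError("build_segmented_spectra requires at least one window")
    if mask.shape != (cube.height, cube.width):
        raise CubeError(f"mask shape {mask.shape} does not match cube {cube.height}x{cube.width}")
    inside = np.zeros(cube.n_channels, dtype=bool)
    for w in windows:
        inside[cube.axis.window_indices(w)] = True
    if not inside.any():
        raise CubeError("no window overlaps the cube axis")
    data = np.full_like(cube.data, fill_value)
    data[:, :, inside] = cube.data[:, :, inside]
    return SegmentedCube(
        data=data,
        axis=cube.axis,
        windows=list(windows),
        fill_value=fill_value,
        mask=mask,
        window_channels=np.nonzero(inside)[0],
    )


def mask_fraction(mask: PixelMask) -> float:
    return mask.fraction()


def segment_cube(
    cube: HyperCube,
    bands: list[BandWindow],
    threshold: ThresholdSpec = ThresholdSpec(),
    morph: MorphSpec = MorphSpec(),
    stat: str = "max",
) -> tuple[PixelMask, list[IntensityMap]]:
    """Full default segmentation: per-band map → binarize → morph → merge."""
    maps = [band_intensity_map(cube, band, stat) for band in bands]
    masks = [morph_clean(binarize(m, threshold), morph) for m in maps]
    return merge_masks(masks), maps
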