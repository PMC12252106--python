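"""Post-unmixing analysis: exclusive masks, average spectra, difference
spectra, spatial SNR, confocal resolution, and group statistics.

The spatial SNR follows the per-pixel definition SNR = S/σ_y, where S is
the height of the strongest band above the (already subtracted) baseline
and σ_y is the population standard deviation of S over the 3×3
neighborhood including the center, truncated at image borders.  Pixels
with σ_y = 0 are marked undefined.  Quantitative work is generally
considered unreliable below SNR = 2.

Lateral and axial confocal resolution follow the diffraction-limited
forms Δx = Δy = 0.61 λ/NA and Δz = 0.89 λ/NA².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cube import BandWindow, CubeError, HyperCube, PixelMask, Spectrum
from .preprocess import DrplsParams, baseline_drpls
from .segmentation import ThresholdSpec, resolve_threshold
from .unmixing import AbundanceStack

__all__ = [
    "AverageSpectrumResult",
    "SNRMap",
    "ResolutionResult",
    "GroupTestReport",
    "exclusive_masks",
    "average_spectrum",
    "normalize_subtract",
    "snr_map",
    "resolution",
    "group_test",
]


@dataclass
class AverageSpectrumResult:
    spectrum: Spectrum
    n_pixels: int
    mask: PixelMask


@dataclass
class SNRMap:
    values: np.ndarray  # H×W, S/σy (0 where undefined)
    s_map: np.ndarray  # per-pixel band height S
    undefined_mask: np.ndarray  # σy == 0


@dataclass(frozen=True)
class ResolutionResult:
    lambda_nm: float
    na: float
    dx_nm: float
    dz_nm: float


@dataclass
class GroupTestReport:
    shapiro_p: tuple[float, float]
    levene_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    alpha: float
    significant: bool


def exclusive_masks(
    stack: AbundanceStack, spec: ThresholdSpec = ThresholdSpec("percentile", 75.0)
) -> list[PixelMask]:
    """Binarize each abundance map, then drop pixels claimed by 2+ maps.

    Thresholds are resolved per map over the masked-pixel values (unmasked
    pixels are structurally 0 and would skew percentile/Otsu levels).  The
    returned masks are pairwise disjoint by construction.
    """
    p = stack.maps.shape[2]
    inside = stack.mask.flags
    binaries = []
    for j in range(p):
        vals = stack.maps[:, :, j]
        thr = resolve_threshold(vals[inside], spec) if inside.any() else resolve_threshold(vals, spec)
        binaries.append((vals > thr) & inside)
    overlap = np.sum(binaries, axis=0) >= 2
    out: list[PixelMask] = []
    for j, flags in enumerate(binaries):
        cleaned = flags & ~overlap
        removed = int((flags & overlap).sum())
        if flags.any() and not cleaned.any():
            warnings.warn(
                f"exclusive mask {j} emptied by intersection removal "
                f"({removed} overlapping pixels)",
                stacklevel=2,
            )
        out.append(
            PixelMask(
                cleaned,
                [f"exclusive:map={j}:method={spec.method}:removed_overlap={removed}"],
            )
        )
    return out


def component_support(
    stack: AbundanceStack, index: int, floor: float = 1e-6
) -> PixelMask:
    """Pixels where one endmember's abundance is meaningfully present.

    Abundance maps are zero-inflated and span orders of magnitude (exact
    zeros from the non-negativity constraint, a noise-leakage population,
    an enriched population, rare nearly-pure pixels).  Exact zeros carry
    no information about present-vs-absent and are dropped; the class
    boundary among the positive coefficients is found by Otsu in the log
    domain, where the populations are comparably spaced.  A linear-domain
    Otsu would latch onto the rare nearly-pure pixels and miss the
    enriched population.
    """
    vals = stack.maps[:, :, index]
    inside = stack.mask.flags
    from skimage.filters import threshold_otsu

    pos = vals[inside]
    pos = pos[pos > floor]
    if pos.size < 2 or np.ptp(np.log10(pos)) == 0:
        return PixelMask(np.zeros_like(inside), [f"support:map={index}:empty"])
    thr = 10.0 ** float(threshold_otsu(np.log10(pos)))
    flags = (vals > thr) & inside
    return PixelMask(flags, [f"support:map={index}:log_otsu={thr:.6g}"])


def average_spectrum(cube: HyperCube, mask: PixelMask) -> AverageSpectrumResult:
    """Channel-wise arithmetic mean over masked pixels."""
    if mask.shape != (cube.height, cube.width):
        raise CubeError(f"mask shape {mask.shape} does not match cube")
    if mask.count == 0:
        raise CubeError("average_spectrum requires a non-empty mask")
    ys, xs = np.nonzero(mask.flags)
    mean = cube.data[ys, xs, :].mean(axis=0)
    return AverageSpectrumResult(Spectrum(cube.axis, mean), int(ys.size), mask)


def _resample(reference: Spectrum, axis) -> np.ndarray:
    """Linear interpolation of the reference onto a target axis."""
    wn_ref = reference.axis.wavenumbers
    y_ref = reference.intensities
    if not reference.axis.ascending:
        wn_ref, y_ref = wn_ref[::-1], y_ref[::-1]
    return np.interp(axis.wavenumbers, wn_ref, y_ref)


def normalize_subtract(
    avg: Spectrum,
    reference: Spectrum,
    window: BandWindow | None = None,
    baseline_params: DrplsParams | None = DrplsParams(),
) -> Spectrum:
    """Difference spectrum for minority-component detection.

    Both spectra are baseline-corrected (unless ``baseline_params`` is
    None), max-normalized to 1 within ``window`` (global max by default),
    and subtracted: result = avg − reference.  A residual band that
    survives this subtraction flags a contribution absent from the
    reference.
    """
    if reference.axis == avg.axis:
        ref_y = reference.intensities
    else:
        ref_y = _resample(reference, avg.axis)
    a, r = avg.intensities, ref_y
    if baseline_params is not None:
        a = baseline_drpls(avg, baseline_params).corrected.intensities
        r = baseline_drpls(Spectrum(avg.axis, r), baseline_params).corrected.intensities
    if window is not None:
        idx = avg.axis.window_indices(window)
        if idx.size == 0:
            raise CubeError("normalization window does not overlap the axis")
    else:
        idx = np.arange(len(avg.axis))
    ma, mr = float(a[idx].max()), float(r[idx].max())
    if ma <= 0 or mr <= 0:
        raise CubeError("cannot max-normalize a spectrum with non-positive window maximum")
    return Spectrum(avg.axis, a / ma - r / mr)


def snr_map(cube: HyperCube) -> SNRMap:
    """Spatial SNR = S/σy on a baseline-corrected cube.

    σy is the population standard deviation (ddof=0) of S over the 3×3
    neighborhood including the center, truncated at image borders.
    """
    s = cube.data.max(axis=2)
    h, w = s.shape
    padded = np.full((h + 2, w + 2), np.nan)
    padded[1:-1, 1:-1] = s
    stacked = np.stack(
        [padded[dy : dy + h, dx : dx + w] for dy in range(3) for dx in range(3)], axis=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma = np.nanstd(stacked, axis=0, ddof=0)
    undefined = sigma == 0
    values = np.zeros_like(s)
    np.divide(s, sigma, out=values, where=~undefined)
    values = np.clip(values, 0.0, None)
    return SNRMap(values=values, s_map=s, undefined_mask=undefined)


def resolution(lambda_nm: float, na: float) -> ResolutionResult:
    """Diffraction-limited confocal resolution: Δx=0.61λ/NA, Δz=0.89λ/NA²."""
    if not lambda_nm > 0:
        raise CubeError(f"excitation wavelength must be positive, got {lambda_nm}")
    if not (0 < na <= 1.7):
        raise CubeError(f"numerical aperture must be in (0, 1.7], got {na}")
    return ResolutionResult(
        lambda_nm=float(lambda_nm),
        na=float(na),
        dx_nm=0.61 * lambda_nm / na,
        dz_nm=0.89 * lambda_nm / na**2,
    )


def group_test(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> GroupTestReport:
    """Fixed two-group pipeline: Shapiro–Wilk, Levene, Mann–Whitney U.

    The normality/variance checks are reported but do not gate the
    non-parametric test; significance is decided by the two-sided
    Mann–Whitney p-value against ``alpha``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise CubeError(f"each group needs n >= 3, got {a.size} and {b.size}")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    lev = stats.levene(a, b).pvalue
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestReport(
        shapiro_p=(float(sw_a), float(sw_b)),
        levene_p=float(lev),
        mannwhitney_u=float(mw.statistic),
        mannwhitney_p=float(mw.pvalue),
        alpha=float(alpha),
        significant=bool(mw.pvalue < alpha),
    )
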