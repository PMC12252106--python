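"""Seedable phantom hyperspectral cubes with ground truth.

The generator emulates two-component electrospun-fiber Raman images: a
majority polymer matrix plus a minority compound placed on a fiber
pattern, with pseudo-Voigt bands at literature positions, a smooth
fluorescence-like baseline, additive Gaussian noise, and 1–2-channel
cosmic-ray spikes.  Three presets mirror the studied systems:

* ``pla_ha`` — 64.3% polylactic acid / 35.7% hydroxyapatite, the HA
  concentrated as beads on the PLA fibers;
* ``pcl_collagen`` — 98% polycaprolactone / 2% collagen, the collagen
  enriched in diffuse low-level regions along the fibers;
* ``pla_pva`` — 95% PLA / 5% polyvinyl alcohol, the PVA in small
  punctual regions.

Pixel spectra follow the linear mixing model
``cube = Σ_i A_i(x, y) · E_i(ν) + baseline + noise`` where the effective
coefficients ``A_i = g · a_i`` combine compositional fractions ``a_i``
(which average to the nominal mass fraction over fiber pixels) with a
smooth per-pixel brightness field ``g`` standing in for fiber thickness
and focus.  Nominal mass fractions are used directly as mean abundance
fractions; real Raman cross-sections are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube import BandWindow, CubeError, HyperCube, SpectralAxis, Spectrum

__all__ = [
    "BandSpec",
    "ComponentSpec",
    "BaselineSpec",
    "SceneSpec",
    "PhantomTruth",
    "make_endmember",
    "make_phantom",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center (cm⁻¹), FWHM (cm⁻¹), relative height, shape."""

    center: float
    fwhm: float
    height: float
    shape: str = "pseudo_voigt"
    eta_mix: float = 0.5  # Lorentzian fraction for pseudo-Voigt

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if not self.height > 0:
            raise ValueError("height must be positive")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wn: np.ndarray) -> np.ndarray:
        x = wn - self.center
        gauss = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        lorentz = 1.0 / (1.0 + (2.0 * x / self.fwhm) ** 2)
        if self.shape == "gaussian":
            base = gauss
        elif self.shape == "lorentzian":
            base = lorentz
        else:
            base = self.eta_mix * lorentz + (1.0 - self.eta_mix) * gauss
        return self.height * base


@dataclass(frozen=True)
class ComponentSpec:
    bands: tuple[BandSpec, ...]
    fraction: float

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")


@dataclass(frozen=True)
class BaselineSpec:
    kind: str = "polynomial"  # or "sigmoid"
    amplitude: float = 0.3  # relative to unit peak height
    coeffs: tuple[float, ...] = (0.5, 0.6, -0.4)  # polynomial in t = (ν-lo)/(hi-lo)

    def shape(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "polynomial":
            return self.amplitude * sum(c * t**k for k, c in enumerate(self.coeffs))
        if self.kind == "sigmoid":
            return self.amplitude / (1.0 + np.exp(-8.0 * (t - 0.6)))
        raise ValueError(f"unknown baseline kind {self.kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a phantom scene; a pure function of this spec
    (seed included) produces the cube."""

    components: dict[str, ComponentSpec]
    matrix: str
    minority: str
    height: int = 50
    width: int = 50
    wn_start: float = 300.0
    wn_stop: float = 3500.0
    wn_step: float = 2.0
    step_xy: float = 1.0
    fiber_pattern: str = "lines"  # lines | beads_on_lines | diffuse_blobs | punctual
    fiber_coverage: float = 0.2
    line_width: int = 3
    minority_level: float = 0.9  # in-support minority fraction
    region_radius: float = 2.5  # bead/blob/spot radius, pixels
    brightness_range: tuple[float, float] = (0.6, 1.0)
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    baseline_spatial_jitter: float = 0.2  # relative spread of the baseline amplitude field
    noise_sigma: float = 0.01  # additive Gaussian SD, units of unit peak height
    spike_count: int = 0
    spike_amplitude: float = 5.0
    seed: int = 0
    pure_pixels_per_component: int = 3
    segmentation_windows: tuple[BandWindow, ...] = ()
    intensity_bands: dict[str, BandWindow] = field(default_factory=dict)
    reference_windows: dict[str, tuple[BandWindow, ...]] = field(default_factory=dict)
    normalize_window: BandWindow | None = None
    minority_marker_cm1: float | None = None

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=seed)

    def axis(self) -> SpectralAxis:
        n = int(round((self.wn_stop - self.wn_start) / self.wn_step)) + 1
        return SpectralAxis(self.wn_start + self.wn_step * np.arange(n))


@dataclass
class PhantomTruth:
    """Ground truth of a phantom cube."""

    endmember_spectra: dict[str, Spectrum]
    fractions: dict[str, np.ndarray]  # compositional fractions a_i (sum to 1 on fiber)
    abundance_fields: dict[str, np.ndarray]  # effective coefficients g * a_i
    brightness: np.ndarray
    fiber_mask: np.ndarray
    support_masks: dict[str, np.ndarray]
    spike_records: list[tuple[int, int, int]]  # (x, y, channel)
    baseline_cube: np.ndarray


def make_endmember(bands: tuple[BandSpec, ...] | list[BandSpec], axis: SpectralAxis) -> Spectrum:
    """Sum of band profiles on the axis, max-normalized to 1."""
    if not bands:
        raise CubeError("make_endmember requires at least one band")
    wn = axis.wavenumbers
    lo, hi = float(wn.min()), float(wn.max())
    y = np.zeros(len(axis))
    used = 0
    for band in bands:
        if not (lo <= band.center <= hi):
            warnings.warn(
                f"band at {band.center} cm-1 outside axis [{lo}, {hi}]; skipped",
                stacklevel=2,
            )
            continue
        y += band.profile(wn)
        used += 1
    if used == 0 or y.max() <= 0:
        raise CubeError("no band overlaps the axis; cannot build an endmember")
    return Spectrum(axis, y / y.max())


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return mask
    from scipy.ndimage import binary_dilation

    se = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return binary_dilation(mask, structure=se)


def _draw_fiber_lines(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Random straight fibers, clipped along their length to reach the
    requested coverage (up to a few pixels).

    Each fiber is the square dilation of a 1-pixel core line, so the fiber
    set is a union of structuring-element translates: a morphological
    opening with the same (line_width) kernel preserves it exactly, as it
    does real fibers thicker than the cleanup kernel.
    """
    h, w = spec.height, spec.width
    target_px = int(round(spec.fiber_coverage * h * w))
    radius = max(0, spec.line_width // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    fiber = np.zeros((h, w), dtype=bool)
    stall = 0
    for _ in range(50 * h):
        have = int(fiber.sum())
        if have >= target_px or stall > 20:
            break
        theta = rng.uniform(0.0, np.pi)
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        dist = np.abs((xx - cx) * np.sin(theta) - (yy - cy) * np.cos(theta))
        core = dist <= 0.5
        if not core.any():
            stall += 1
            continue
        need = target_px - have
        line = _dilate(core, radius)
        n_new = int((line & ~fiber).sum())
        if n_new == 0:
            stall += 1
            continue
        if n_new <= need:
            fiber |= line
            stall = 0
            continue
        # clip the core along its direction so the dilated segment fits
        t = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        cys, cxs = np.nonzero(core)
        order = np.argsort(t[cys, cxs], kind="stable")
        lo_k, hi_k = 0, order.size
        best: np.ndarray | None = None
        while lo_k < hi_k:  # largest core prefix whose dilation still fits
            mid = (lo_k + hi_k + 1) // 2 if lo_k + 1 < hi_k else hi_k
            part = np.zeros((h, w), dtype=bool)
            keep = order[:mid]
            part[cys[keep], cxs[keep]] = True
            added = _dilate(part, radius) & ~fiber
            if int(added.sum()) <= need:
                best = added
                lo_k = mid
                if mid == hi_k:
                    break
            else:
                hi_k = mid - 1
        if best is not None and best.any():
            fiber |= best
            stall = 0
        else:
            stall += 1
    return fiber


def _place_regions(
    spec: SceneSpec, fiber: np.ndarray, target_px: int, rng: np.random.Generator
) -> np.ndarray:
    """Disks of radius region_radius centered on fiber pixels; the last
    disk is trimmed (farthest pixels dropped) to hit target_px exactly."""
    h, w = fiber.shape
    yy, xx = np.mgrid[0:h, 0:w]
    fy, fx = np.nonzero(fiber)
    support = np.zeros_like(fiber)
    r2 = spec.region_radius**2
    for _ in range(10 * max(1, target_px)):
        have = int(support.sum())
        if have >= target_px:
            break
        k = int(rng.integers(fy.size))
        cy, cx = int(fy[k]), int(fx[k])
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = (d2 <= r2) & fiber
        new = disk & ~support
        need = target_px - have
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if n_new <= need:
            support |= disk
        else:
            ys, xs = np.nonzero(new)
            order = np.argsort(d2[ys, xs], kind="stable")
            keep = order[:need]
            support[ys[keep], xs[keep]] = True
    return support


def _smooth_field(shape: tuple[int, int], lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field linearly mapped to [lo, hi]."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    rmin, rmax = raw.min(), raw.max()
    if rmax <= rmin:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (raw - rmin) / (rmax - rmin)


def make_phantom(spec: SceneSpec) -> tuple[HyperCube, PhantomTruth]:
    """Generate a phantom cube and its ground truth (pure function of spec)."""
    fractions = {name: c.fraction for name, c in spec.components.items()}
    if sum(fractions.values()) <= 0:
        raise CubeError("component fractions are all zero")
    if spec.matrix not in spec.components or spec.minority not in spec.components:
        raise CubeError("matrix/minority names must be component keys")
    rng = np.random.default_rng(spec.seed)
    axis = spec.axis()
    h, w, b = spec.height, spec.width, len(axis)

    endmembers = {
        name: make_endmember(c.bands, axis) for name, c in spec.components.items()
    }

    fiber = _draw_fiber_lines(spec, rng)
    n_fiber = int(fiber.sum())
    if n_fiber < 4:
        raise CubeError("fiber coverage too low: fewer than 4 fiber pixels")

    f_min = spec.components[spec.minority].fraction / sum(fractions.values())
    if spec.fiber_pattern == "lines":
        support = fiber.copy()
    else:
        target = int(round(np.clip(f_min / spec.minority_level, 0.0, 1.0) * n_fiber))
        target = max(target, 1)
        support = _place_regions(spec, fiber, target, rng)

    # pure pixels: a few bright, fully pure pixels per component so the
    # extreme-pixel search can recover exact signatures
    k_pure = min(spec.pure_pixels_per_component, max(0, int(support.sum()) - 1))
    sy, sx = np.nonzero(support)
    pure_min_idx = rng.choice(sy.size, size=k_pure, replace=False) if k_pure else np.empty(0, int)
    matrix_only = fiber & ~support
    my, mx = np.nonzero(matrix_only)
    k_pure_mat = min(spec.pure_pixels_per_component, my.size)
    pure_mat_idx = (
        rng.choice(my.size, size=k_pure_mat, replace=False) if k_pure_mat else np.empty(0, int)
    )

    # minority compositional fraction field with exact mean over fiber pixels
    a_min = np.zeros((h, w))
    budget = f_min * n_fiber
    n_support = int(support.sum())
    level = spec.minority_level if spec.fiber_pattern != "lines" else f_min
    if n_support > k_pure:
        level = (budget - k_pure) / (n_support - k_pure)
        level = float(np.clip(level, 0.0, 0.95))
    a_min[support] = level
    a_min[sy[pure_min_idx], sx[pure_min_idx]] = 1.0
    a_maj = np.where(fiber, 1.0 - a_min, 0.0)

    brightness = _smooth_field((h, w), *spec.brightness_range, rng)
    brightness[~fiber] = 0.0
    brightness[sy[pure_min_idx], sx[pure_min_idx]] = 1.0
    brightness[my[pure_mat_idx], mx[pure_mat_idx]] = 1.0

    a_fields = {spec.matrix: a_maj, spec.minority: a_min}
    abundance = {name: brightness * a for name, a in a_fields.items()}

    t = (axis.wavenumbers - spec.wn_start) / (spec.wn_stop - spec.wn_start)
    base_shape = spec.baseline.shape(t)
    j = spec.baseline_spatial_jitter
    amp_field = (
        _smooth_field((h, w), 1.0 - j, 1.0 + j, rng) if j > 0 else np.ones((h, w))
    )
    baseline_cube = amp_field[:, :, None] * base_shape[None, None, :]

    data = baseline_cube.copy()
    for name in spec.components:
        data += abundance[name][:, :, None] * endmembers[name].intensities[None, None, :]
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=(h, w, b))

    spikes: list[tuple[int, int, int]] = []
    for _ in range(spec.spike_count):
        py = int(rng.integers(h))
        px = int(rng.integers(w))
        pc = int(rng.integers(1, b - 2))
        width = 2 if rng.random() < 0.3 else 1
        amp = spec.spike_amplitude * (0.5 + rng.random())
        for dc in range(width):
            data[py, px, pc + dc] += amp * (1.0 - 0.4 * dc)
            spikes.append((px, py, pc + dc))

    cube = HyperCube(data, axis, spec.step_xy, {"phantom": True, "seed": spec.seed})
    truth = PhantomTruth(
        endmember_spectra=endmembers,
        fractions=a_fields,
        abundance_fields=abundance,
        brightness=brightness,
        fiber_mask=fiber,
        support_masks={spec.matrix: fiber & ~support, spec.minority: support},
        spike_records=spikes,
        baseline_cube=baseline_cube,
    )
    return cube, truth


# ---------------------------------------------------------------------------
# scenario presets (band positions from the studied compounds' Raman spectra)

_PLA_BANDS = (
    BandSpec(2935, 30, 1.0),
    BandSpec(2871, 30, 0.65),
    BandSpec(2991, 28, 0.5),
    BandSpec(1766, 24, 0.4),
    BandSpec(1450, 26, 0.35),
    BandSpec(1385, 24, 0.2),
    BandSpec(1046, 20, 0.25),
    BandSpec(873, 18, 0.45),
    BandSpec(406, 20, 0.2),
    BandSpec(309, 22, 0.15),
)

_HA_BANDS = (
    BandSpec(959, 14, 1.0),
    BandSpec(1041, 18, 0.15),
    BandSpec(588, 18, 0.12),
    BandSpec(433, 18, 0.1),
)

_PCL_BANDS = (
    BandSpec(2905, 34, 1.0),
    BandSpec(2865, 30, 0.6),
    BandSpec(1719, 18, 0.3),
    BandSpec(1438, 26, 0.35),
    BandSpec(1298, 22, 0.3),
    BandSpec(1106, 20, 0.12),
    BandSpec(958, 18, 0.15),
    BandSpec(913, 18, 0.18),
)

_COLLAGEN_BANDS = (
    BandSpec(2924, 30, 1.0),
    BandSpec(1659, 36, 0.45),
    BandSpec(1446, 30, 0.3),
    BandSpec(1260, 30, 0.22),
    BandSpec(933, 24, 0.12),
    BandSpec(851, 22, 0.12),
)

_PVA_BANDS = (
    BandSpec(2900, 34, 1.0),
    BandSpec(3378, 60, 0.3),
    BandSpec(1718, 20, 0.12),
    BandSpec(1440, 30, 0.3),
    BandSpec(1090, 26, 0.18),
    BandSpec(912, 22, 0.15),
    BandSpec(851, 20, 0.1),
    BandSpec(629, 20, 0.12),
)


def _scene_pla_ha() -> SceneSpec:
    return SceneSpec(
        components={
            "PLA": ComponentSpec(_PLA_BANDS, 0.643),
            "HA": ComponentSpec(_HA_BANDS, 0.357),
        },
        matrix="PLA",
        minority="HA",
        fiber_pattern="beads_on_lines",
        fiber_coverage=0.32,
        minority_level=0.9,
        region_radius=2.5,
        spike_count=30,
        segmentation_windows=(BandWindow(2800, 3050), BandWindow(930, 990)),
        intensity_bands={"PLA": BandWindow(2915, 2955), "HA": BandWindow(944, 974)},
        reference_windows={
            "PLA": (BandWindow(2915, 2955), BandWindow(1746, 1786), BandWindow(853, 893)),
            "HA": (BandWindow(939, 979), BandWindow(568, 608)),
        },
        normalize_window=None,
        minority_marker_cm1=959.0,
    )


def _scene_pcl_collagen() -> SceneSpec:
    return SceneSpec(
        components={
            "PCL": ComponentSpec(_PCL_BANDS, 0.98),
            "collagen": ComponentSpec(_COLLAGEN_BANDS, 0.02),
        },
        matrix="PCL",
        minority="collagen",
        fiber_pattern="diffuse_blobs",
        fiber_coverage=0.22,
        minority_level=0.1,
        region_radius=3.0,
        spike_count=30,
        segmentation_windows=(
            BandWindow(2800, 3000),
            BandWindow(1690, 1750),
            BandWindow(1630, 1690),
        ),
        intensity_bands={
            "PCL": BandWindow(1699, 1739),
            "collagen": BandWindow(1639, 1679),
        },
        reference_windows={
            "PCL": (BandWindow(1699, 1739), BandWindow(2885, 2925)),
            "collagen": (BandWindow(1639, 1679), BandWindow(2904, 2944)),
        },
        normalize_window=BandWindow(2800, 3000),
        minority_marker_cm1=2924.0,
    )


def _scene_pla_pva() -> SceneSpec:
    return SceneSpec(
        components={
            "PLA": ComponentSpec(_PLA_BANDS, 0.95),
            "PVA": ComponentSpec(_PVA_BANDS, 0.05),
        },
        matrix="PLA",
        minority="PVA",
        fiber_pattern="punctual",
        fiber_coverage=0.15,
        minority_level=0.8,
        region_radius=1.6,
        spike_count=30,
        segmentation_windows=(BandWindow(2800, 3050),),
        intensity_bands={"PLA": BandWindow(386, 426), "PVA": BandWindow(609, 649)},
        reference_windows={
            "PLA": (BandWindow(2915, 2955), BandWindow(2971, 3011)),
            "PVA": (BandWindow(2880, 2912),),
        },
        normalize_window=BandWindow(2800, 3050),
        minority_marker_cm1=2900.0,
    )


SCENARIOS = {
    "pla_ha": _scene_pla_ha,
    "pcl_collagen": _scene_pcl_collagen,
    "pla_pva": _scene_pla_pva,
}


def scenario(name: str) -> SceneSpec:
    """Preset scene for one of the studied fiber systems."""
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise CubeError(
            f"unknown scenario {name!r}; presets: {sorted(SCENARIOS)}"
        ) from None
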