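"""Core data types for Raman hyperspectral cubes, spectra, masks and maps.

A hyperspectral cube holds an H×W image of Raman spectra on a common
wavenumber axis (cm⁻¹).  Pixels are addressed as (x=column, y=row), origin
top-left, and linearized in y-major order (flat index = y*W + x).  Band
windows are expressed in wavenumbers, inclusive on both bounds, so all
band logic works for ascending as well as descending instrument axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "CubeError",
    "SpectralAxis",
    "BandWindow",
    "Spectrum",
    "HyperCube",
    "PixelMask",
    "IntensityMap",
    "crop_bands",
]


class CubeError(ValueError):
    """Structured error for cube/axis/shape contract violations."""


@dataclass(frozen=True)
class SpectralAxis:
    """Per-channel Raman shift axis in cm⁻¹, strictly monotonic."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        if wn.ndim != 1 or wn.size < 1:
            raise CubeError("spectral axis must be 1-D with at least 1 channel")
        if not np.all(np.isfinite(wn)):
            raise CubeError("spectral axis contains non-finite values")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CubeError("spectral axis must be strictly monotonic")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def ascending(self) -> bool:
        return bool(self.wavenumbers[-1] > self.wavenumbers[0])

    def window_indices(self, window: "BandWindow") -> np.ndarray:
        """Channel indices with lo <= wavenumber <= hi (inclusive both ends)."""
        wn = self.wavenumbers
        idx = np.nonzero((wn >= window.lo) & (wn <= window.hi))[0]
        return idx

    def nearest_channel(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def __eq__(self, other: object) -> bool:  # value equality
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.array_equal(self.wavenumbers, other.wavenumbers)
        )


@dataclass(frozen=True)
class BandWindow:
    """Wavenumber interval [lo, hi] in cm⁻¹, inclusive on both bounds."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise CubeError(f"band window requires lo < hi, got [{self.lo}, {self.hi}]")

    def overlaps(self, axis: SpectralAxis) -> bool:
        return self.lo <= float(np.max(axis.wavenumbers)) and self.hi >= float(
            np.min(axis.wavenumbers)
        )


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum: intensities (arbitrary units) on an axis."""

    axis: SpectralAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1 or y.size != len(self.axis):
            raise CubeError(
                f"intensity length {y.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise CubeError("spectrum contains non-finite intensities")


@dataclass
class HyperCube:
    """H×W×B hyperspectral image with wavenumber axis and spatial pitch (µm)."""

    data: np.ndarray
    axis: SpectralAxis
    step_xy: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise CubeError(f"cube data must be 3-D (H, W, B), got shape {self.data.shape}")
        h, w, b = self.data.shape
        if h < 1 or w < 1:
            raise CubeError(f"cube spatial shape must be >= 1x1, got {h}x{w}")
        if b != len(self.axis):
            raise CubeError(
                f"cube channel count {b} does not match axis length {len(self.axis)}"
            )
        if not self.step_xy > 0:
            raise CubeError(f"step_xy must be positive, got {self.step_xy}")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def pixel(self, x: int, y: int) -> Spectrum:
        return Spectrum(self.axis, self.data[y, x])

    def flat(self) -> np.ndarray:
        """(H*W, B) view in y-major pixel order (index = y*W + x)."""
        return self.data.reshape(-1, self.n_channels)

    def copy(self) -> "HyperCube":
        return HyperCube(self.data.copy(), self.axis, self.step_xy, dict(self.meta))


@dataclass
class PixelMask:
    """Boolean H×W pixel selection with a provenance trail."""

    flags: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise CubeError(f"mask must be 2-D, got shape {self.flags.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def fraction(self) -> float:
        """count(true) / count(all)."""
        return float(self.flags.mean())

    def with_step(self, op: str, flags: np.ndarray) -> "PixelMask":
        return PixelMask(flags, self.provenance + [op])


@dataclass
class IntensityMap:
    """Per-pixel summary intensity of one band window."""

    values: np.ndarray
    band: BandWindow

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CubeError(f"intensity map must be 2-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def crop_bands(cube: HyperCube, window: BandWindow) -> HyperCube:
    """Crop the cube to channels inside `window` (inclusive both bounds).

    The returned cube owns a copy of the selected channels; cropping twice
    with the same window is idempotent.
    """
    idx = cube.axis.window_indices(window)
    if idx.size == 0:
        raise CubeError(
            f"band window [{window.lo}, {window.hi}] does not overlap the "
            f"axis range [{cube.axis.wavenumbers.min()}, {cube.axis.wavenumbers.max()}]"
        )
    axis = SpectralAxis(cube.axis.wavenumbers[idx].copy())
    return HyperCube(cube.data[:, :, idx].copy(), axis, cube.step_xy, dict(cube.meta))
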