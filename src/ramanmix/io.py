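"""Readers and writers for cubes, spectra, masks and maps.

Canonical on-disk cube format is ``matrix_csv_json``: a matrix CSV whose
rows are pixels in y-major order (row index = y*W + x) and whose columns
are spectral channels, next to a JSON sidecar (same path with a ``.json``
suffix) holding ``height``, ``width``, ``axis``, ``step_xy`` and ``meta``.
Floats are written with 17 significant digits so the round trip is
bit-exact.  A long-format CSV (columns x, y, wavenumber, intensity) is
supported for interoperability; spectra are two-column CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import BandWindow, CubeError, HyperCube, IntensityMap, PixelMask, SpectralAxis, Spectrum

__all__ = [
    "CUBE_FORMATS",
    "read_cube",
    "write_cube",
    "read_spectrum",
    "write_spectrum",
    "read_mask",
    "write_mask",
    "read_map",
    "write_map",
    "export_png",
]

CUBE_FORMATS = ("matrix_csv_json", "long_table")

_FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: HyperCube, path: str | Path, format: str = "matrix_csv_json") -> Path:
    """Write a cube; read_cube(write_cube(c)) is bit-exact for matrix_csv_json."""
    path = Path(path)
    if not np.all(np.isfinite(cube.data)):
        raise CubeError("refusing to write cube containing non-finite intensities")
    if format == "matrix_csv_json":
        np.savetxt(path, cube.flat(), delimiter=",", fmt=_FLOAT_FMT)
        sidecar = {
            "height": cube.height,
            "width": cube.width,
            "axis": cube.axis.wavenumbers.tolist(),
            "step_xy": cube.step_xy,
            "meta": cube.meta,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    elif format == "long_table":
        h, w, b = cube.data.shape
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        df = pd.DataFrame(
            {
                "x": np.repeat(xx.ravel(), b),
                "y": np.repeat(yy.ravel(), b),
                "wavenumber": np.tile(cube.axis.wavenumbers, h * w),
                "intensity": cube.flat().ravel(),
            }
        )
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    else:
        raise CubeError(f"unsupported cube format {format!r}; supported: {CUBE_FORMATS}")
    return path


def read_cube(path: str | Path, format: str = "matrix_csv_json") -> HyperCube:
    """Read a cube written by :func:`write_cube` (or compatible files)."""
    path = Path(path)
    if format == "matrix_csv_json":
        sidecar_file = _sidecar_path(path)
        if not sidecar_file.exists():
            raise CubeError(f"missing JSON sidecar {sidecar_file} for matrix CSV cube")
        sidecar = json.loads(sidecar_file.read_text())
        h, w = int(sidecar["height"]), int(sidecar["width"])
        axis = SpectralAxis(np.asarray(sidecar["axis"], dtype=float))
        mat = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        if mat.shape[0] != h * w:
            raise CubeError(
                f"pixel count mismatch: CSV has {mat.shape[0]} rows, "
                f"sidecar declares height*width = {h * w}"
            )
        if mat.shape[1] != len(axis):
            raise CubeError(
                f"channel count mismatch: CSV has {mat.shape[1]} columns, "
                f"sidecar axis has {len(axis)} channels"
            )
        return HyperCube(
            mat.reshape(h, w, len(axis)),
            axis,
            float(sidecar.get("step_xy", 1.0)),
            dict(sidecar.get("meta", {})),
        )
    if format == "long_table":
        df = pd.read_csv(path)
        required = {"x", "y", "wavenumber", "intensity"}
        if not required.issubset(df.columns):
            raise CubeError(
                f"long table must have columns {sorted(required)}, got {list(df.columns)}"
            )
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        w, h = xs.size, ys.size
        # preserve the per-pixel channel order of the file for the axis
        first_pixel = df[(df["x"] == xs[0]) & (df["y"] == ys[0])]
        axis = SpectralAxis(first_pixel["wavenumber"].to_numpy(dtype=float))
        b = len(axis)
        if len(df) != h * w * b:
            raise CubeError(
                f"long table row count {len(df)} does not equal "
                f"height*width*channels = {h}*{w}*{b}"
            )
        data = np.empty((h, w, b), dtype=float)
        df = df.sort_values(["y", "x"], kind="stable")
        data[...] = df["intensity"].to_numpy(dtype=float).reshape(h, w, b)
        return HyperCube(data, axis)
    raise CubeError(f"unsupported cube format {format!r}; supported: {CUBE_FORMATS}")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    arr = np.column_stack([spectrum.axis.wavenumbers, spectrum.intensities])
    np.savetxt(path, arr, delimiter=",", fmt=_FLOAT_FMT, header="wavenumber,intensity")
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[1] != 2:
        raise CubeError(f"spectrum file must have 2 columns, got {arr.shape[1]}")
    return Spectrum(SpectralAxis(arr[:, 0]), arr[:, 1])


def write_mask(mask: PixelMask, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, mask.flags.astype(int), delimiter=",", fmt="%d")
    return path


def read_mask(path: str | Path) -> PixelMask:
    flags = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2).astype(bool)
    return PixelMask(flags, [f"read:{Path(path).name}"])


def write_map(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt=_FLOAT_FMT)
    return path


def read_map(path: str | Path, band: BandWindow | None = None) -> IntensityMap:
    values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    return IntensityMap(values, band if band is not None else BandWindow(0.0, 1.0))


def export_png(values: np.ndarray, path: str | Path) -> Path:
    """8-bit grayscale PNG export for display (min-max scaled)."""
    from PIL import Image

    values = np.asarray(values, dtype=float)
    lo, hi = float(np.nanmin(values)), float(np.nanmax(values))
    scaled = np.zeros_like(values) if hi <= lo else (values - lo) / (hi - lo)
    img = Image.fromarray((np.nan_to_num(scaled) * 255).astype(np.uint8), mode="L")
    path = Path(path)
    img.save(path)
    return path
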