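"""Endmember extraction (N-FINDR) and abundance estimation.

N-FINDR searches for the p pixels whose simplex in a (p−1)-dimensional
reduced spectral space has maximal volume; those pixels are taken as the
purest available signatures (endmembers).  Reduction is PCA to p−1
components.  Abundances are per-pixel non-negative least-squares (NNLS)
coefficients on the endmember signatures, max-normalized per map for
display; with the constant fill value outside the segmentation windows the
fill channels act as a soft sum-to-one constraint, so dim/noise pixels
load onto the noise endmember rather than inflating component maps.

For a two-compound fiber the recommended endmember count is
n_compounds + 1: the extra vertex captures the noise signature of the
image, which is then identified by :func:`label_endmembers`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import PCA

from .cube import BandWindow, CubeError, PixelMask
from .segmentation import SegmentedCube

__all__ = [
    "ReducedData",
    "EndmemberSet",
    "AbundanceStack",
    "reduce_pixels",
    "simplex_volume",
    "nfindr",
    "abundances",
    "abundances_from_bands",
    "label_endmembers",
]


@dataclass
class ReducedData:
    """PCA-reduced masked pixels: N×(p−1) coords plus the projection basis."""

    coords: np.ndarray  # (N, p-1)
    basis: np.ndarray  # (p-1, B)
    mean: np.ndarray  # (B,)
    pixel_index: np.ndarray  # (N, 2) (x, y) per row
    explained_variance: np.ndarray


@dataclass
class EndmemberSet:
    count: int
    spectra: np.ndarray  # (p, B) signatures on the spectral axis
    pixel_ids: np.ndarray  # (p, 2) source pixel (x, y)
    volume: float

    def __post_init__(self) -> None:
        if self.count < 2:
            raise CubeError("an endmember set needs p >= 2")
        ids = {tuple(r) for r in np.asarray(self.pixel_ids)}
        if len(ids) != self.count:
            raise CubeError("endmember source pixels must be distinct")
        if self.volume < 0:
            raise CubeError("simplex volume must be non-negative")


@dataclass
class AbundanceStack:
    maps: np.ndarray  # (H, W, p), values in [0, 1]
    endmembers: EndmemberSet | None
    method: str
    mask: PixelMask
    names: list[str] | None = None


def reduce_pixels(
    pixels: np.ndarray, p: int, pixel_index: np.ndarray | None = None
) -> ReducedData:
    """Mean-center and project masked-pixel spectra to p−1 principal components."""
    pixels = np.asarray(pixels, dtype=float)
    n = pixels.shape[0]
    if p < 2:
        raise CubeError("endmember count p must be >= 2")
    if n < p:
        raise CubeError(f"need at least p={p} pixels, got {n}")
    if np.allclose(pixels, pixels[0]):
        raise CubeError("degenerate pixel set: all pixels identical")
    pca = PCA(n_components=p - 1, svd_solver="full")
    coords = pca.fit_transform(pixels)
    if pixel_index is None:
        pixel_index = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    return ReducedData(
        coords=coords,
        basis=pca.components_,
        mean=pca.mean_,
        pixel_index=np.asarray(pixel_index),
        explained_variance=pca.explained_variance_,
    )


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume of the simplex spanned by p points in p−1 dimensions.

    |det(edge matrix)| / (p−1)!; degenerate (collinear, coplanar, ...) sets
    return 0.
    """
    v = np.asarray(vertices, dtype=float)
    p = v.shape[0]
    if p < 2:
        raise CubeError("a simplex needs at least 2 vertices")
    if v.shape[1] != p - 1:
        raise CubeError(f"{p} vertices must live in {p - 1} dimensions, got {v.shape[1]}")
    edges = v[1:] - v[0]
    return float(abs(np.linalg.det(edges)) / factorial(p - 1))


def _aug(coords: np.ndarray) -> np.ndarray:
    """Augmented rows [1, x...]: |det| of p such rows = (p−1)! * volume."""
    return np.column_stack([np.ones(coords.shape[0]), coords])


def _row_cofactors(a: np.ndarray, j: int) -> np.ndarray:
    """Cofactor vector of row j, so det(A with row j -> r) = r @ cof."""
    p = a.shape[0]
    minor_rows = [i for i in range(p) if i != j]
    cof = np.empty(p)
    for k in range(p):
        minor_cols = [c for c in range(p) if c != k]
        minor = a[np.ix_(minor_rows, minor_cols)]
        cof[k] = ((-1) ** (j + k)) * (np.linalg.det(minor) if minor.size else 1.0)
    return cof


def nfindr(
    reduced: ReducedData,
    spectra: np.ndarray,
    p: int,
    seed: int = 0,
    restarts: int = 10,
) -> EndmemberSet:
    """Simplex-volume maximization by vertex-replacement sweeps.

    Each restart seeds a random vertex set, then repeatedly tests every
    pixel in every vertex slot, accepting the replacement that most
    increases the simplex volume (strict increase, so sweeps terminate).
    The best of ``restarts`` restarts is returned; deterministic for a
    fixed seed.
    """
    coords = reduced.coords
    n = coords.shape[0]
    if n < p:
        raise CubeError(f"N-FINDR needs at least p={p} pixels, got {n}")
    if coords.shape[1] != p - 1:
        raise CubeError(
            f"reduced coordinates have {coords.shape[1]} dims; expected p-1={p - 1}"
        )
    aug = _aug(coords)
    fac = factorial(p - 1)
    best_idx: np.ndarray | None = None
    best_vol = -1.0
    for r in range(restarts):
        rng = np.random.default_rng([int(seed), r])
        idx = rng.choice(n, size=p, replace=False)
        vol = abs(np.linalg.det(aug[idx])) / fac
        improved = True
        while improved:
            improved = False
            for slot in range(p):
                cof = _row_cofactors(aug[idx], slot)
                cand_vols = np.abs(aug @ cof) / fac
                cand_vols[idx] = -np.inf  # keep vertices distinct
                k = int(np.argmax(cand_vols))
                if cand_vols[k] > vol:
                    idx[slot] = k
                    vol = float(cand_vols[k])
                    improved = True
        if vol > best_vol:
            best_vol = vol
            best_idx = idx.copy()
    assert best_idx is not None
    order = np.argsort(best_idx)  # stable canonical ordering of vertices
    best_idx = best_idx[order]
    return EndmemberSet(
        count=p,
        spectra=np.asarray(spectra, dtype=float)[best_idx].copy(),
        pixel_ids=reduced.pixel_index[best_idx].copy(),
        volume=float(best_vol),
    )


def abundances(
    segmented: SegmentedCube,
    endmembers: EndmemberSet,
    mask: PixelMask | None = None,
    method: str = "nnls",
) -> AbundanceStack:
    """Per-pixel abundance coefficients on the endmember signatures.

    ``nnls`` (default): non-negative least squares, no sum-to-one
    constraint.  ``lstsq``: unconstrained projection with negative
    coefficients clipped to zero (for comparison).  Each map is
    max-normalized to [0, 1]; unmasked pixels are 0.
    """
    if mask is None:
        mask = segmented.mask
    e = endmembers.spectra.T  # (B, p)
    p = endmembers.count
    if np.linalg.matrix_rank(e) < p:
        raise CubeError("endmember matrix is rank-deficient")
    h, w = mask.shape
    maps = np.zeros((h, w, p))
    ys, xs = np.nonzero(mask.flags)
    if method == "nnls":
        for y, x in zip(ys, xs):
            coef, _ = nnls(e, segmented.data[y, x])
            maps[y, x] = coef
    elif method == "lstsq":
        sol, *_ = np.linalg.lstsq(e, segmented.data[ys, xs].T, rcond=None)
        maps[ys, xs] = np.clip(sol.T, 0.0, None)
    else:
        raise CubeError(f"unknown abundance method {method!r}; use 'nnls' or 'lstsq'")
    for j in range(p):
        m = maps[:, :, j].max()
        if m > 0:
            maps[:, :, j] /= m
    return AbundanceStack(maps=maps, endmembers=endmembers, method=method, mask=mask)


def abundances_from_bands(
    cube,
    bands: dict[str, BandWindow],
    mask: PixelMask,
    stat: str = "max",
) -> AbundanceStack:
    """Traditional abundance mapping from exclusive-band intensities."""
    from .segmentation import band_intensity_map

    names = list(bands)
    h, w = mask.shape
    maps = np.zeros((h, w, len(names)))
    for j, name in enumerate(names):
        im = band_intensity_map(cube, bands[name], stat)
        vals = np.where(mask.flags, np.clip(im.values, 0.0, None), 0.0)
        m = vals.max()
        if m > 0:
            vals = vals / m
        maps[:, :, j] = vals
    return AbundanceStack(
        maps=maps, endmembers=None, method="band_intensity", mask=mask, names=names
    )


def label_endmembers(
    endmembers: EndmemberSet,
    references: dict[str, list[BandWindow]],
    axis,
    active_channels: np.ndarray | None = None,
    k: float = 5.0,
    rel_floor: float = 0.1,
) -> list[str]:
    """Name each endmember after the reference whose bands it exhibits.

    A window is "matched" when its peak score (max minus the signature
    median) exceeds both k times the robust noise scale of the signature
    and ``rel_floor`` times the largest score in the whole endmember set;
    an endmember with no matched window is labeled ``"noise"``.

    Statistics are computed over the active (in-window) channels — with a
    constant fill value outside the segmentation windows a whole-signature
    MAD degenerates to 0.  The noise scale is the MAD of channel-to-channel
    differences (insensitive to smooth band structure, which would inflate
    a plain MAD and suppress broad-band signatures); because smoothing
    correlates neighboring channels and deflates that estimate, the
    relative floor provides the judgment that a noise signature "lacks
    Raman bands" compared with the real endmembers.  Ties go to the
    reference with more matched windows, then lexicographic.
    """
    if not references:
        raise CubeError("label_endmembers requires at least one reference")
    # reference windows only count where the signature carries data: with
    # segmented spectra, channels outside the retained windows hold the
    # constant fill value and must not score
    active_set = (
        set(int(c) for c in active_channels)
        if active_channels is not None and active_channels.size
        else None
    )
    # first pass: raw window scores and per-signature noise scales
    all_scores: list[dict[str, list[float]]] = []
    noise_scales: list[float] = []
    for s in endmembers.spectra:
        if active_set is not None:
            act = s[np.asarray(sorted(active_set))]
        else:
            act = s
        med = float(np.median(act))
        d = np.diff(act)
        noise_scales.append(float(np.median(np.abs(d - np.median(d)))) / 0.6745 / np.sqrt(2.0))
        per_ref: dict[str, list[float]] = {}
        for name, windows in references.items():
            scores = []
            for wdw in windows:
                idx = axis.window_indices(wdw)
                if active_set is not None:
                    idx = np.asarray([i for i in idx if int(i) in active_set], dtype=int)
                if idx.size == 0:
                    continue
                scores.append(float(s[idx].max() - med))
            per_ref[name] = scores
        all_scores.append(per_ref)
    best_overall = max(
        (sc for per_ref in all_scores for scores in per_ref.values() for sc in scores),
        default=0.0,
    )
    labels: list[str] = []
    for per_ref, mad in zip(all_scores, noise_scales):
        floor = max(k * mad, rel_floor * best_overall)
        scored: list[tuple[float, int, str]] = []
        for name, scores in per_ref.items():
            matched = [sc for sc in scores if sc > floor]
            if matched:
                scored.append((max(matched), len(matched), name))
        if not scored:
            labels.append("noise")
        else:
            # largest peak score; ties -> more matched windows -> lexicographic
            scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
            labels.append(scored[0][2])
    return labels
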