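# Methods

This note documents the models and procedures implemented in `ramanmix`,
the parameter choices that matter, what the phantom generator does and
does not emulate, and the package's known limitations.

## Data model

A hyperspectral cube is an H×W image of Raman spectra on a shared,
strictly monotonic wavenumber axis (cm⁻¹). Pixels are addressed (x=column,
y=row) with origin top-left and linearized y-major (flat index = y·W + x).
All band logic works on wavenumber *values*, inclusive on both window
bounds, so ascending and descending instrument axes behave identically.
The canonical on-disk format is a matrix CSV (rows = pixels, columns =
channels, 17 significant digits) plus a JSON sidecar with height, width,
axis, pixel pitch and metadata; the round trip is bit-exact. A long-format
CSV (x, y, wavenumber, intensity) is supported for interoperability. No
claim is made of compatibility with any vendor's raw files.

## Preprocessing

**Despiking.** Cosmic rays are 1–2-channel transients. Candidates are
channels adjacent to first differences whose modified z-score
`0.6745·(∇y − median ∇y)/MAD` exceeds `z_threshold` (default 6, chosen
conservatively to spare sharp Raman bands; exposed in config). Because a
single spike inflates the differences on *both* sides, the raw rule also
flags the innocent neighbor; and because a narrow band sampled at ~2 cm⁻¹
produces long runs of large differences, the raw rule would flatten real
structure. Both failure modes are removed by confirmation: only candidate
runs of ≤ 4 channels are eligible (a 2-channel burst plus one innocent
flag per side), and within a run a channel is a spike only if it deviates
from the linear interpolation between the run's clean anchors by more
than the robust noise scale. Confirmed channels are replaced by the mean
of non-flagged neighbors within ±`window` (default 3) channels; all other
channels are returned bit-identical. If the MAD of the differences is 0
(flat or perfectly regular spectra) nothing is flagged and the condition
is reported.

**Smoothing.** Savitzky–Golay (scipy), default window 9 / order 3 —
preserves bands ≥ 8 cm⁻¹ FWHM at ~1–2 cm⁻¹ sampling. Edges are handled
by polynomial fit on the truncated window (`mode="interp"`). The filter
is linear and reproduces polynomials up to the fit order exactly; on
white noise it reduces interior variance by the sum of squared
coefficients (≈ 0.21 for 11/2).

**Baseline.** Doubly reweighted penalized least squares (drPLS): solve
`(W + (I − ηW)·λDᵀD) z = W y` with D the second-difference operator,
then update the weights through a sigmoid of the residuals whose slope
grows with the iteration index, using the negative-residual statistics as
the noise reference. Defaults λ = 10⁵, η = 0.5, max 100 iterations,
tolerance 10⁻³, all overridable. The system is pentadiagonal and solved
with a banded solver (the penalty matrix is cached per (B, λ)). Iteration
stops when the weights *or the baseline itself* change by less than the
tolerance — the latter guards against slow weight erosion on peak-free
spectra, where the fit is exact from the first iteration but the weight
sequence never settles. Non-convergence returns the last iterate with a
flag rather than raising. The estimate is exactly invariant to adding a
constant (the penalty annihilates constants and the residuals are
unchanged).

Stages run in the fixed order despike → smooth → baseline, per pixel; the
same corrected cube feeds both abundance-mapping routes so their
comparison is like-for-like.

## Segmentation

One intensity map per discriminating band (per-pixel max over the window
by default; sum available), binarized at a threshold (default: 75th
percentile of the map — scale-free across cubes; Otsu and absolute
levels available; the mask keeps values strictly above the threshold),
cleaned morphologically, and merged by union (sum ≥ 1, binarize again).
The published cleanup kernel of 1×1 is available but is the identity; the
library default is an opening (erode-then-dilate) with kernel 3, which
actually removes isolated anomalous pixels. The scenario pipeline presets
use kernel 1 deliberately: with it, masks built from a minority band
retain isolated noise pixels, and the extra N-FINDR vertex then lands on
a genuine noise signature — the behavior the method is designed to
surface and label. Retained windows are spliced into synthetic spectra
that equal the corrected cube inside the windows and a constant fill
value outside; the fill defaults to 1 (the published convention), with 0
available because a constant offset changes the simplex geometry: with
fill 1, the fill channels act as a soft sum-to-one constraint in the
abundance fit, which is why dim and noise pixels load onto the noise
endmember instead of inflating component maps.

## Unmixing

Masked segmented spectra are mean-centered and projected onto the first
p−1 principal components (PCA is the standard reduction companion of
N-FINDR). N-FINDR seeds p random vertices and repeatedly tests every
pixel in every vertex slot, accepting the replacement that most increases
the simplex volume `|det(edges)|/(p−1)!`; strict increase guarantees
termination, volumes are evaluated by cofactor expansion so a full sweep
is vectorized, and the best of 10 restarts (seeded, bit-reproducible) is
returned. p defaults to the number of expected compounds + 1, so the
noise vertex is modeled explicitly. On all enumerable instances tested
(N ≤ 25, p = 3), the sweep search returns the same vertex set as
exhaustive search.

Abundances are per-pixel NNLS coefficients on the endmember signatures —
"projection" without a sum-to-one constraint; unconstrained least squares
with clipping is available behind a flag for comparison. Each map is
max-normalized to [0, 1]; unmasked pixels are 0. The traditional
exclusive-band-intensity maps are computed alongside through the same
interface, because comparing the two routes is the point of the method.

**Labeling.** Each endmember signature is scored against named reference
band windows (restricted to the channels the segmentation retained — the
fill value must not score). A window is matched when its peak score
(window max minus the in-window median) exceeds both k (default 5) times
the signature's robust noise scale — the MAD of channel-to-channel
differences, insensitive to smooth band structure — and 10% of the
largest score in the whole endmember set. The relative floor encodes the
judgment that a noise signature "lacks Raman bands" *compared with the
real endmembers*; it is needed because smoothing correlates neighboring
channels and deflates difference-based noise estimates. An endmember with
no matched window is labeled "noise"; ties go to the reference with more
matched windows, then lexicographically.

## Post-analysis

**Exclusive masks and averages.** Each abundance map is binarized
(default: 75th percentile over masked pixels) and every pixel claimed by
two or more maps is removed from all, leaving pairwise disjoint masks;
channel-wise means over those masks give the per-component average
spectra, with the pixel counts reported.

**Minority detection.** The average spectrum of the minority region and
the matrix reference are baseline-corrected (optional), max-normalized to
1 within a chosen window (the C–H stretching region in the presets, the
global max otherwise), and subtracted. A residual band surviving the
subtraction flags a contribution absent from the reference; the pipeline
reports the wavenumber of the largest |residual| within the window.
`component_support` extracts the minority's spatial support from its
abundance map by Otsu in the log domain after dropping exact zeros:
abundance maps are zero-inflated and span orders of magnitude (NNLS noise
leakage, an enriched population, rare nearly-pure pixels), and a
linear-domain Otsu latches onto the rare pure pixels.

**Spatial SNR.** Per pixel, S is the maximum of the baseline-corrected
spectrum; σ_y is the population standard deviation (ddof = 0) of S over
the 3×3 neighborhood *including the center*, truncated at image borders —
a declared convention, covered by a hand-computed test. SNR = S/σ_y;
pixels with σ_y = 0 are marked undefined. The map is invariant to
positive rescaling of the cube. SNR < 2 marks pixels where quantitative
analysis is not considered feasible.

**Resolution.** Δx = Δy = 0.61 λ/NA and Δz = 0.89 λ/NA², exact to
machine precision, rounded only for display. (Published resolution
figures for NA-0.75 optics sometimes correspond to NA 0.4 under these
same formulas; the package exposes the formulas only and takes no side.)

**Group statistics.** Shapiro–Wilk per group and Levene across groups are
computed and reported but do not gate the decision; significance is the
two-sided Mann–Whitney U p-value against α. The pipeline is deliberately
fixed, not adaptive, mirroring how such intensity comparisons are run in
practice. Monte-Carlo calibration at n = 30/30: empirical type-I error
≈ 5%, power ≈ 1 at a 3-SD shift.

## Phantom generator

Scenes follow a linear mixing model: pixel spectrum = Σᵢ Aᵢ(x,y)·Eᵢ(ν) +
baseline + noise, with effective coefficients Aᵢ = g·aᵢ splitting into
compositional fractions aᵢ (exactly the nominal mass fraction on average
over fiber pixels) and a smooth brightness field g ∈ [0.6, 1] standing in
for fiber thickness and focus. Endmembers are sums of pseudo-Voigt bands
(η = 0.5) at literature band positions for PLA, HA, PCL, collagen and
PVA, max-normalized. Fibers are square dilations of random 1-pixel line
cores (so a morphological opening with the matching kernel preserves them
exactly, as it does real fibers thicker than the cleanup kernel), clipped
to the requested coverage. Minority placement: pure beads (PLA/HA,
level 0.9), diffuse enriched regions (PCL/collagen, level ≈ 0.1),
punctual spots (PLA/PVA, level 0.8); each scene also plants a few bright
fully-pure pixels per component (default 3) so extreme-pixel searches
have exact signatures to find, with the remaining support rescaled to
keep the mean fraction exact. The baseline is a smooth polynomial or
sigmoid shape (amplitude 0.3 of unit peak) modulated by a smooth spatial
field (±20% by default; settable to 0 for fully deterministic
backgrounds). Noise is additive Gaussian, default σ = 0.01 of unit peak
height (1%); cosmic rays are 1–2-channel spikes of ~5× peak amplitude at
recorded positions. The generator is a pure function of the scene spec,
seed included.

Preset study conditions: 50×50 pixels, axis 300–3500 cm⁻¹ at 2 cm⁻¹
(1601 channels) — sized so a full pipeline run takes seconds; mass
fractions 64.3/35.7 (PLA/HA), 98/2 (PCL/collagen), 95/5 (PLA/PVA); fiber
coverages 0.32 / 0.22 / 0.15 matching the spatial character of the three
systems; 30 spikes per cube.

**What passing on phantoms does not show.** The generator emulates
neither Raman cross-sections (mass fractions are used directly as mean
abundance fractions, so "2%" means 2% of the signal, not calibrated
concentration), nor shot noise, detector nonlinearity, wavenumber
calibration error, confocal blur, focal drift, nor fluorescent compounds
that swamp the bands. Results on real instruments with these effects may
be worse, particularly for very thin fibers whose signal scales with the
sampled volume.

## Numerical and design choices

- Thresholding is strict (`>`); percentile thresholds are computed on the
  relevant value population (whole map for segmentation, masked pixels
  for abundance maps).
- N-FINDR ties during sweeps are broken by `argmax` (first maximum);
  restart ties keep the earlier restart; vertices are reported sorted by
  pixel index — all deterministic.
- Degenerate inputs raise structured `CubeError`s naming the offending
  dimension (shape mismatches, non-monotonic axes, empty masks, rank-
  deficient endmember matrices, all-identical pixel sets).
- The pipeline report is serialized with sorted keys; identical config
  and seed reproduce it byte-for-byte.

## Limitations

- Two-component scenes are first-class; n-component fibers are supported
  in principle via p = n + 1 but only two-component presets are tested.
- ENVI and vendor binary formats are not read; convert to the CSV formats
  first.
- The exclusive-mask construction can empty a component's mask when two
  abundance maps coincide (a warning reports the overlap count).
- Abundances are relative display quantities in [0, 1], not calibrated
  concentrations; no correction for multiple testing is applied across
  the fixed set of tested wavenumbers.
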