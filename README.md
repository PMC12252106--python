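# ramanmix

Chemical-heterogeneity mapping of composite electrospun fibers from Raman
hyperspectral images, using only open-source building blocks.

Electrospun scaffolds often carry a minority compound (hydroxyapatite,
collagen, polyvinyl alcohol, ...) blended into a polymer matrix (PLA, PCL).
Bulk Raman spectra hide *where* that compound sits; hyperspectral imaging can
reveal it, but the minority component may contribute only 2–5% of the mass
and lack strong exclusive bands. `ramanmix` implements a full analysis chain
for this problem:

1. **Preprocessing** per pixel spectrum: Whitaker–Hayes-style cosmic-ray
   despiking (modified z-scores of first differences, with a narrow-run
   confirmation step), Savitzky–Golay smoothing, and doubly reweighted
   penalized-least-squares (drPLS) baseline correction.
2. **Segmentation**: band-intensity maps at each compound's discriminating
   band, threshold binarization (absolute / percentile / Otsu), morphological
   cleanup, and mask merging; the retained band windows are spliced into
   "synthetic spectra" with a constant fill value of 1 outside the windows.
3. **Unmixing**: N-FINDR endmember extraction — the p masked pixels whose
   simplex in (p−1)-dimensional PCA space has maximal volume

       V(e_1, …, e_p) = |det[e_2−e_1, …, e_p−e_1]| / (p−1)!

   with p = (number of compounds) + 1 so the extra vertex captures the image
   noise — followed by per-pixel non-negative least squares (NNLS) abundances
   on the endmember signatures.
4. **Post-analysis**: mutually exclusive abundance masks and average spectra,
   normalize-and-subtract difference spectra that expose minority bands, the
   spatial signal-to-noise ratio SNR = S/σ_y (band height over the standard
   deviation of neighboring pixels' band heights; quantitation is unreliable
   below SNR = 2), confocal resolution Δx = 0.61 λ/NA and Δz = 0.89 λ/NA²,
   and Shapiro–Wilk / Levene / Mann–Whitney group comparisons.
5. **Phantoms**: a seedable generator of ground-truthed fiber scenes
   (pseudo-Voigt bands at literature positions, fluorescence-like baselines,
   Gaussian noise, cosmic-ray spikes) with presets for PLA/HA (35.7%
   beads-on-fibers), PCL/collagen (2%, diffuse regions) and PLA/PVA (5%,
   punctual spots), so every stage is testable without instrument data.

## Worked example

Run the full pipeline on the PLA/PVA phantom (95% PLA, 5% PVA in punctual
regions):

```python
from ramanmix import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(scenario="pla_pva", seed=1, out_dir="out"))
print(result.report)
```

prints (abridged):

```json
{
  "endmember_labels": ["PLA", "PVA", "noise"],
  "mask_fraction": 0.25,
  "n_masked_pixels": 625,
  "n_pixels_per_average": {"0:PLA": 142, "1:PVA": 119, "2:noise": 133},
  "difference_peak_cm1": 2900.0,
  "snr": {"median_masked": 8.09, "fraction_below_2": 0.048},
  "spike_count": 43
}
```

Reading: 25% of pixels carried chemical information; of the three extracted
endmembers, two are identified as PLA and PVA and the third as the noise
signature of the image. Subtracting the normalized PLA average spectrum from
the PVA-region average leaves its largest residual at 2900 cm⁻¹ — the
symmetric C–H stretch of PVA — i.e. the 5% minority component is detected
from a band region shared by both polymers. The median spatial SNR of 8.1
puts most masked pixels well above the SNR = 2 quantifiability bound.

The same chain is available from the shell:

```bash
ramanmix simulate --scenario pla_pva --seed 1 --out phantom/
ramanmix preprocess --in phantom/cube.csv --out corrected.csv
ramanmix segment --in corrected.csv --band 2800:3050 --threshold percentile:75 \
    --morph open:1 --out-mask mask.csv
ramanmix unmix --in corrected.csv --mask mask.csv --band 2800:3050 \
    --endmembers 3 --seed 1 --out-endmembers em.csv --out-abundance abun.csv
ramanmix resolution --lambda 532 --na 0.75
# {"dx_nm": 432.69..., "dy_nm": 432.69..., "dz_nm": 841.74...}
```

## Layout

- `src/ramanmix/cube.py`, `io.py` — data types (cube, spectrum, mask, map,
  band window) and the CSV/JSON on-disk formats (y-major pixel order,
  flat index = y·W + x).
- `src/ramanmix/preprocess.py` — despike, smooth, drPLS baseline.
- `src/ramanmix/segmentation.py` — maps, thresholds, morphology, segmented
  spectra.
- `src/ramanmix/unmixing.py` — PCA reduction, simplex volume, N-FINDR,
  NNLS abundances, endmember labeling.
- `src/ramanmix/postanalysis.py` — exclusive masks, averages, difference
  spectra, SNR, resolution, group tests.
- `src/ramanmix/synthcube.py` — phantom generator and scenario presets.
- `src/ramanmix/pipeline.py`, `cli.py` — end-to-end orchestration and the
  `ramanmix` command.

See `docs/methods.md` for the models, parameter choices, and limitations.
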