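# hsiph

Near-infrared hyperspectral-imaging chemometrics for determining and
**mapping the pH of anaerobic-digestion liquid**.

pH is one of the main levers of anaerobic digestion (and hence methane
yield), but a pH meter reads one spot per dish. A hyperspectral camera
records a full NIR spectrum at every pixel, so a calibration model built on
dish-mean spectra against reference pH readings can be applied per pixel,
turning each scene into a pH distribution map. `hsiph` implements that
workflow end to end for researchers in biomass process monitoring and NIR
chemometrics:

* **Reflectance calibration** of raw cubes with white/dark references,
  `R = (I_r − I_d)/(I_w − I_d)`, plus a minimal ENVI raster/header codec;
* **ROI extraction**: Otsu + largest-component + erosion segmentation of
  the Petri-dish interior (the rim has alien spectral features);
* **Preprocessing**: per-pixel wavelet denoising (db5, level 5, universal
  soft threshold), denoise-then-average sample spectra, 1042.16–1578.13 nm
  working range (160 bands), seeded 2:1 calibration/prediction split with
  range coverage;
* **Wavelength selection**: successive projections algorithm (SPA),
  random frog (10,000 iterations), and VIP scores
  `v_j = sqrt(p Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` with threshold 1.21;
* **Calibration**: NIPALS PLS1 (LV count by 5-fold CV) and a three-layer
  backpropagation network with hidden width chosen from
  `round(√(m+n)) + a, a = 1…10`; scored by r_c/r_p and RMSEC/RMSEP;
* **Mapping**: pixel-wise prediction with out-of-range flagging and PNG
  rendering;
* **Phantom generator**: Petri-dish scenes with pH-dependent Gaussian
  absorption features, compositional jitter, scan-level drift and pixel
  noise, so the whole chain is testable without instrument data.

## Worked example

```python
import numpy as np
from hsiph import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=1,
                     selection_methods=("spa",), models=("pls", "bpnn"),
                     map_model="spa+bpnn")
manifest = run_pipeline(cfg)
for row in manifest["stages"]["train"]["metrics"]:
    print(f"{row['model']:<10} {row['size']:<9} "
          f"r_c={row['r_c']:.3f} RMSEC={row['RMSEC']:.4f} "
          f"r_p={row['r_p']:.3f} RMSEP={row['RMSEP']:.4f}")
print("map MAE vs truth:", round(manifest["stages"]["map"]["map_mae_vs_truth"], 4))
```

On the default phantom study (93 samples, pixel noise SD 0.005) this prints:

```
full+pls   13 LVs    r_c=0.984 RMSEC=0.0173 r_p=0.933 RMSEP=0.0308
full+bpnn  20 nodes  r_c=1.000 RMSEC=0.0000 r_p=0.904 RMSEP=0.0498
spa+pls    7 LVs     r_c=0.979 RMSEC=0.0199 r_p=0.921 RMSEP=0.0341
spa+bpnn   4 nodes   r_c=0.986 RMSEC=0.0163 r_p=0.928 RMSEP=0.0328
map MAE vs truth: 0.023
```

Reading: models predict dish pH with r_p ≈ 0.92–0.93 and RMSEP ≈ 0.03 pH
— close to the phantom's noise floor (the compositional jitter and scan
drift are irreducible) — and the 8 SPA-selected bands do as well as all
160 (a 95 % band reduction). The full-spectrum BPNN memorises the
calibration set (r_c = 1.000) yet still generalises worst: the usual
overfitting signature. The pixel-wise map recovers the true per-pixel pH
to ~0.02 pH mean absolute error; `demo_run/ph_map.png` shows the rendered
map, with extrapolating pixels (predictions outside the calibration pH
range) in a sentinel colour.

The same workflow runs from the shell:

```bash
hsiph run-all --config config.yaml      # or: python -m hsiph run-all ...
```

with subcommands `simulate`, `calibrate`, `extract`, `train`, `evaluate`,
`map` for the individual stages. Every run writes a `manifest.json` with
seeds, configuration, metric tables and SHA-256 hashes of all artifacts;
identical configs reproduce identical hashes.

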