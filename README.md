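# leafspec

Non-destructive estimation of pesticide residues (mg/kg) on lettuce
leaves, combining reflectance spectroscopy with machine-vision imaging
under a single characteristic wavelength.

Surface residues of a systemic insecticide such as imidacloprid subtly
change a leaf's reflectance. The workflow implemented here exploits
that twice: first a spectrometer survey (320–1100 nm, 1 nm resolution)
locates the **characteristic wavelength** — the band whose absorbance
proxy log₁₀(1/R) correlates most strongly with residue concentration,
and which loads most heavily on the retained principal components of
the standardized spectra. Once that band is known, expensive
spectrometry is no longer needed: photographs taken under a matching
bandpass filter and light source carry the same information, and a
small convolutional network maps per-leaf image statistics to the
residue concentration measured by reference chemistry (LC-MS/MS).

The package is aimed at chemometrics and agricultural-imaging
practitioners who want to reproduce, probe or extend this pipeline.
Because no public lettuce/imidacloprid dataset exists, a first-class
synthetic module generates spectra (with a planted residue-dependent
absorption band, multiplicative scatter and channel noise) and leaf
images (a lit leaf disk on a dark background whose channel statistics
rise monotonically with concentration), so every stage is testable.

## What is inside

| stage | module | core idea |
|---|---|---|
| preprocessing | `leafspec.preprocess` | the eight calibration-study schemes: raw, per-spectrum min-max y=(x−x_min)/(x_max−x_min), MSC, plain first derivative, Savitzky–Golay smoothing and SG 1st/2nd convolution derivatives via the projection B = X(XᵀX)⁻¹Xᵀ, mean centering |
| band selection | `leafspec.wavelengths` | Pearson correlation curve of log₁₀(1/R) against residue + PCA scoring coefficients; peak screening with a minimum band separation |
| calibration | `leafspec.chemometrics` | NIPALS PLS1 with Rc/SEC (calibration) and Rp/SEP (prediction) on an 8:2 split; preprocessing-ranking and full-band vs characteristic-band comparisons |
| imaging | `leafspec.imaging` | BT.601 grayscale, Otsu segmentation + 3×3 closing/opening, background removal, and the 10 foreground statistics (average gray; per-channel mean, SD, CV) |
| regression | `leafspec.cnn` | 6×6 feature grid → conv 2×2×16 → maxpool 2×2 → conv 2×2×32 → dense 512 → dense 1, ReLU throughout, trained by seeded gradient descent (lr 0.01, 10,000 iterations, MSE loss) |
| evaluation | `leafspec.metrics` | PRESS, RMSE, MAE, R² per split |
| simulation | `leafspec.datasets` | planted-band spectra and concentration-linked leaf images |

All model-like components are scikit-learn estimators
(`PLS1Regression`, `CharacteristicBandSelector`, `CNNFeatureRegressor`,
and transformer classes for each preprocessing scheme), so they compose
with sklearn pipelines and model selection.

## Worked example

```python
import numpy as np
from leafspec.datasets import SpectraSimConfig, ImageSimConfig, generate_dataset
from leafspec.imaging import extract_features
from leafspec.wavelengths import CharacteristicBandSelector
from leafspec.cnn import CNNFeatureRegressor, CNNConfig
from leafspec.metrics import rmse, r2

spectra, images, _, conc = generate_dataset(
    SpectraSimConfig(seed=3), ImageSimConfig(seed=4), n=1200)

sel = CharacteristicBandSelector(wavelengths=spectra.spectra.wavelengths)
sel.fit(spectra.spectra.values, spectra.concentrations)
print("primary band:", sel.primary_band_, "nm")

X = np.vstack([extract_features(im).to_array() for im in images])
model = CNNFeatureRegressor(config=CNNConfig(seed=5)).fit(X, conc)
yte = conc[model.test_idx_]
yhat = model.predict(X[model.test_idx_])
print("held-out R² = %.3f, RMSE = %.3f mg/kg" % (r2(yte, yhat), rmse(yte, yhat)))
```

prints

```
primary band: 710.0 nm
held-out R² = 1.000, RMSE = 0.019 mg/kg
```

The primary band lands within a few nm of the 709 nm absorption the
generator planted, and the network recovers the held-out
concentrations to ~0.02 mg/kg — far below the 0.15 mg/kg accuracy
that the Chinese national standard for lettuce requires, reflecting
the clean monotone feature–concentration link the simulator encodes.

The same flow is available from the shell:

```bash
leafspec simulate --out ws --n 200 --seed 0
leafspec select-bands --spectra ws/spectra.csv --out ws/bands
leafspec train --images ws/images --labels ws/labels.csv --out ws/run
leafspec predict --model-dir ws/run --image ws/images/leaf_0000.png
```

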