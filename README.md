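# endospect

Hyperspectral reflectance reconstruction and narrow-band image simulation
for white-light endoscopy.

## The problem

Narrow-band imaging (NBI) endoscopes illuminate tissue at the hemoglobin
absorption bands near 415 nm and 540 nm, which sharply enhances mucosal
and submucosal vasculature — the key visual cue for early esophageal
squamous cell carcinoma. Many endoscopes (notably capsule endoscopes)
carry no narrow-band filters. `endospect` reconstructs a full visible-range
reflectance spectrum at every pixel of an ordinary white-light sRGB frame,
then synthesizes an NBI-like composite purely by selecting the 415 nm and
540 nm planes of the reconstructed cube. It also ships the evaluation
battery used to compare imaging modalities: CIEDE2000 vessel/background
color contrast, Shannon entropy, and SSIM.

## The method

Calibration uses a 24-patch color checker imaged by the camera and
measured by a spectrometer. For each patch:

1. **Camera side** — sRGB is gamma-decoded and mapped to tristimulus values
   under the measured source:
   `XYZ = M_A · T · f(RGB) × 100`, with `T` the standard sRGB primaries
   matrix and `M_A` the Bradford chromatic adaptation from D65 to the
   source white.
2. **Spectrometer side** — the source spectrum `S(λ)`, patch reflectance
   `R(λ)` and the CIE 1931 color-matching functions give reference
   tristimulus values `X = k∫S R x̄ dλ` (and likewise Y, Z) with
   `k = 100 / ∫S ȳ dλ`, so a perfect reflector has Y = 100.
3. **Correction** — a multiple regression `C = XYZ_spectrum · pinv(V)` over
   a degree-3 monomial expansion `V` of the camera XYZ absorbs residual
   nonlinearity, crosstalk and color shift.
4. **Spectral basis** — PCA of the 24 measured reflectance spectra yields a
   low-dimensional basis; a second regression `M` maps expanded corrected
   XYZ to principal-component scores. Per pixel,
   `R̂(λ) = mean(λ) + componentsᵀ · M · V(XYZ_correct)`, clipped to [0, 1],
   produces an H×W×401 reflectance cube on the 380–780 nm, 1 nm grid.

Everything is exposed as scikit-learn style estimators:
`SpectralReconstructor` (fit on checker pairs, transform images to cubes)
and `HnbiComposer` (cube → narrow-band composite).

## Worked example

```python
import numpy as np
from endospect import SpectralReconstructor, HnbiComposer
from endospect.synthetic import (SyntheticCheckerConfig, forward_camera,
                                 generate_illuminant, generate_phantom,
                                 generate_reflectance_set)
from endospect.spectral import load_default_cmfs
from endospect.metrics import region_color_difference, shannon_entropy

cmfs = load_default_cmfs()
illum = generate_illuminant("blackbody", T=6504.0)

# synthetic 24-patch checker: matched (sRGB, spectrum) calibration pairs
spectra = generate_reflectance_set(SyntheticCheckerConfig(seed=0))
srgb = forward_camera(spectra, illum, cmfs)

est = SpectralReconstructor(illuminant=illum, cmfs=cmfs, n_components=12)
est.fit(srgb, spectra)
print(f"calibration XYZ RMSE:        {est.xyz_rmse_:.2e}")
print(f"mean spectral RMSE (24 patches): {est.mean_rmse_:.4f}")

scene = generate_phantom(seed=1, size=128, illuminant=illum, cmfs=cmfs)
cube = est.transform(scene.image)          # 128 x 128 x 401 reflectance
hnbi = HnbiComposer().fit().transform(cube)
print(f"vessel/background dE00 (WLI):  {region_color_difference(scene.image, scene.masks):.2f}")
print(f"vessel/background dE00 (HNBI): {region_color_difference(hnbi.pixels, scene.masks):.2f}")
print(f"entropy WLI -> HNBI: {shannon_entropy(scene.image):.2f} -> {shannon_entropy(hnbi.pixels):.2f}")
```

Output:

```
calibration XYZ RMSE:        3.45e-03
mean spectral RMSE (24 patches): 0.0192
vessel/background dE00 (WLI):  9.16
vessel/background dE00 (HNBI): 37.95
entropy WLI -> HNBI: 4.13 -> 4.87
```

The degree-3 correction drives the camera-to-spectrometer XYZ error to
~3e-3 on the noise-free synthetic checker; the residual spectral RMSE of
0.019 reflects the metameric limit of recovering 401 bands from three
color coordinates. The narrow-band composite raises vessel/background
color contrast from 9.2 to 38.0 ΔE00 units — the intended effect of band
selection plus per-plane contrast normalization.

The same workflow is scriptable from the shell:

```sh
endospect simulate  --out fx --seed 3
endospect calibrate --checker fx/checker.csv --illuminant fx/illuminant.csv \
                    --out fx/calib.json --qc fx/qc.json
endospect convert   --image fx/phantom.png --calib fx/calib.json --out fx/cube.hdr
endospect hnbi      --cube fx/cube.hdr --bands 415,540 --map 540:R,415:GB --out fx/hnbi.png
endospect evaluate  --set phantom=fx/phantom.png --set hnbi=fx/hnbi.png \
                    --masks-dir fx --pair sim=phantom/hnbi --out fx/report.csv
```

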