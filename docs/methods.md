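# Methods

## Model

`endospect` treats an endoscope as a colorimetric instrument that can be
calibrated against a spectrometer through a shared 24-patch color
checker, and treats per-pixel reflectance recovery as a regression from
corrected tristimulus values onto a low-dimensional spectral basis.

All spectra live on a fixed grid of 401 samples, 380–780 nm at 1 nm. All
integrals are rectangle-rule sums at the native 1 nm step; the grids are
dense and uniform, so higher-order quadrature would change results by far
less than calibration error, and the fixed rule keeps outputs bit-stable.

**Camera side.** Rendered sRGB values (8-bit values divided by 255) are
gamma-decoded with the IEC 61966-2-1 piecewise function (linear segment
below 0.04045, exponent 2.4 above), mapped through the standard sRGB
primaries matrix `T` — `T` is never estimated from data — and chromatically
adapted from the sRGB D65 white to the measured source white with the
Bradford transform (von Kries and plain XYZ scaling are available). The
source white itself is defined as the tristimulus of a perfect reflector
under the calibration illuminant, which makes the adaptation internally
consistent with the illuminant normalization below.

**Spectrometer side.** The illuminant normalization constant
`k = 100 / Σ S(λ)ȳ(λ)` scales the tristimulus sums so that a unit
reflector has Y = 100 exactly under any non-degenerate illuminant — this
identity is a structural property of the implementation, not a tuned
value.

**Polynomial correction.** Camera XYZ is expanded into all monomials
`X^a Y^b Z^c` with total degree 1–3 plus a constant (20 terms — fewer
than the 24 patches, keeping the least-squares problem determined), and a
3×20 matrix `C` is fitted by pseudoinverse (SVD, relative cutoff 1e-12,
minimum-norm on rank deficiency) to map expanded camera XYZ onto
spectrometer XYZ. The composition of the regressors was an open design
choice; full degree-3 expansion is standard camera-correction practice.

**Spectral reconstruction.** PCA (mean-centered) of the 24 measured
reflectance spectra gives `p` orthonormal components (default `p = 12`,
configurable 2–23: comfortably under the 24 training patches while
capturing smooth natural-reflectance variation). A second least-squares
matrix `M` maps expanded corrected XYZ to component scores; whether that
regression reuses the polynomial expansion or only the linear terms is
configurable (`score_features`), with the polynomial form the default for
consistency with the correction stage. Reconstructed reflectance is
clipped to [0, 1] after basis synthesis and before any re-integration.
Cubes are stored as float32.

## What recovery can and cannot achieve

Three tristimulus coordinates cannot determine 401 free spectral values:
two metameric spectra with identical XYZ are indistinguishable to the
camera by construction. Exact end-to-end recovery is therefore only
well-posed when the spectral variation of the scene is at most
three-dimensional (plus mean). The exact-recovery tests use checker
spectra generated as convex mixtures of four smooth endmembers (a 3-D
affine span); under those conditions, with a noise-free camera and a
linear sensor distortion — whose inverse is a degree-1 polynomial and
hence inside the regressor family — reconstruction is exact to floating
precision. Nonlinear forward distortions generally have non-polynomial
inverses and cannot be inverted exactly by any finite polynomial
regression; the correction then minimizes, not annihilates, the residual.

On unconstrained smooth spectra (the realistic case) the mean per-patch
reflectance RMSE on the synthetic checker is around 0.02 — the metameric
floor, not a numerical defect.

## Narrow-band composition

The 415 nm and 540 nm cube planes are selected by nearest-neighbor index
on the 1 nm grid. Each plane is independently normalized between its 1st
and 99th percentiles (robust to specular highlights; makes the composite
invariant to global positive scaling of the planes), gamma-encoded with
the sRGB transfer function, and routed 540→R, 415→G,B. That channel
routing mirrors the commercial narrow-band display convention in which
superficial microvessels (strong 415 nm absorbers) appear brown and
deeper submucosal vessels appear blue/cyan; it is fully configurable.
Whether real systems contrast-stretch the planes before display is not
public; the percentile normalization here is an explicit assumption.

Preprocessing trims black border rows/columns whose mean 8-bit intensity
falls below 10 (endoscopy mattes are near-zero; threshold configurable),
applies an optional user-supplied crop rectangle for overlay removal
(no OCR), and resizes to 380×380 with bilinear interpolation.

## Metrics

* **CIEDE2000** is implemented in full — a′ chroma rescaling, mean-hue
  weighting `T`, Δθ rotation, `R_C`, `S_L`, `S_C`, `S_H`, and the `R_T`
  hue-rotation term — because the abbreviated top-level form is not
  computable alone. It is validated to 1e-6 against an independent
  reference implementation on random Lab pairs and to 1e-4 on the
  published verification pairs of the formula's authors.
* **Region color contrast** averages Lab within each mask first and
  evaluates one CIEDE2000 between the two mean colors (the alternative —
  averaging pixel-wise differences — is noisier and was not described for
  the original measurements; the mean-color choice is documented here).
* **Entropy** is `H = −Σ p log2 p` over a 256-bin histogram of the
  BT.601 luma plane; the non-negative sign convention is used (entropy is
  non-negative by definition; its 0–8 bit range for 8-bit sources
  confirms the intent of sign-free statements of the formula).
* **SSIM** defaults to the 11×11 Gaussian-windowed form (σ = 1.5,
  C1 = (0.01·255)², C2 = (0.03·255)², population covariance) computed by
  scikit-image behind the package surface; the literal single-window
  global form is available via `mode="global"` and is authored in-package.

## Synthetic data

The generators define the test conditions:

* **Checker spectra**: baseline plus up to four Gaussian bumps
  (amplitudes ±0.30, widths 40–120 nm, centers anywhere in band), clipped
  to [0.02, 0.98]. The optional `rank` parameter mixes patches convexly
  from that many endmembers to confine the affine span (convexity
  preserves the clipping range).
* **Illuminants**: flat, Planck blackbody (default 6504 K, daylight-like),
  or dual-narrowband Gaussian lines at 415/540 nm emulating an NBI source.
* **Camera forward model**: the exact inverse of the calibration chain,
  with optional linear XYZ distortion and multiplicative Gaussian noise
  on linear RGB (default σ = 0.01, approximating shot-noise-dominated
  rendered images).
* **Phantoms**: random-walk vessel strokes 2–6 px wide carrying a
  hemoglobin-like reflectance (0.16-deep dip at 415 nm, 0.10 at 540 nm)
  on a pink mucosa background, plus a smooth illumination falloff, light
  blur and sensor noise. Masks are exact; the background mask excludes a
  3 px guard band around vessels so blur does not contaminate region
  statistics.

What the synthetic fixtures do **not** emulate: true esophageal tissue
optics, Olympus sensor spectral sensitivities, JPEG compression, specular
highlights, motion blur, or inter-patient variability. Passing tests
therefore demonstrate the correctness and self-consistency of the
algorithmic chain, not clinical performance on hospital imagery.

## Numerical and interface choices

* Pseudoinverses use SVD with relative cutoff 1e-12 · largest singular
  value; duplicated regressors degrade gracefully to the minimum-norm
  solution.
* The endoscope-XYZ RMSE in the QC report pools all 3×24 residuals into a
  single value (per-channel reporting would be ambiguous to compare).
* Calibration QC color differences are CIEDE2000 in Lab under the source
  white between re-integrated reconstructed spectra and the spectrometer
  values.
* Coordinates are row-major, top-left origin, 0-based throughout. ENVI
  cubes are BSQ float32 little-endian with the wavelength list embedded
  in the header; reads validate payload size against the header.
* Test and acceptance problem sizes: 24-patch checkers, 64–128 px
  phantoms for unit tests, one full 380×380 frame (380×380×401 cube) in
  the command-line smoke test — large enough to exercise the native frame
  geometry while keeping the default suite fast on one CPU.

## Known limitations

* Recovery quality outside the training gamut degrades quickly: degree-3
  polynomials extrapolate poorly, so scene colors should lie within the
  checker's gamut (the wide-gamut unconstrained checker is the default
  for image conversion for exactly this reason).
* The NBI-source calibration path (narrowband `S(λ)`) is supported but
  untested against hardware; with near-zero illuminant power between the
  lines, mid-band reflectance is unconstrained by the data.
* No raw-sensor (Bayer) processing; input is already-rendered sRGB.
* The 380–780 nm grid is fixed; no fluorescence or infrared extension.
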