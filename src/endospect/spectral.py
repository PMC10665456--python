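"""Spectrometer-side model: tristimulus integration, reflectance basis, cube synthesis.

All spectra live on the fixed visible-range grid 380, 381, ..., 780 nm
(401 samples). Tristimulus values follow the illuminant-normalized
integrals

    k = 100 / sum S(l) ybar(l)
    X = k sum S(l) R(l) xbar(l),   and likewise Y, Z,

evaluated with the rectangle rule at 1 nm steps, so a perfect reflector
always has Y = 100 under any non-degenerate illuminant.

Reflectance reconstruction uses a PCA basis of the 24 training patch
spectra plus a regression M from polynomially expanded corrected XYZ to
the principal-component scores; per-pixel application of that chain turns
an RGB frame into an H x W x 401 reflectance cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from . import colorcal
from .colorcal import CameraCalibration, expand_regressors
from .errors import DomainError, ShapeError, StateError

__all__ = [
    "WAVELENGTHS",
    "N_BANDS",
    "Spectrum",
    "CmfSet",
    "ReflectanceBasis",
    "SpectralTransform",
    "HyperspectralCube",
    "load_default_cmfs",
    "analytic_cmf_table",
    "brightness_constant",
    "spectrum_to_xyz",
    "spectra_to_xyz",
    "source_white_point",
    "fit_reflectance_basis",
    "fit_spectral_transform",
    "reconstruct_spectrum",
    "reconstruct_spectra",
    "image_to_cube",
    "spectra_rmse_report",
]

WAVELENGTHS = np.arange(380.0, 781.0)
N_BANDS = 401

_KINDS = ("reflectance", "illuminant", "cmf")


@dataclass
class Spectrum:
    """A sampled spectrum on the fixed 380-780 nm, 1 nm grid.

    ``kind`` selects the validation rule: reflectance is clipped to [0, 1],
    illuminants must be non-negative, color-matching-function channels are
    unconstrained beyond finiteness.
    """

    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.shape != (N_BANDS,):
            raise ShapeError(f"spectrum must have {N_BANDS} samples, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DomainError("spectrum contains non-finite values")
        if self.kind not in _KINDS:
            raise DomainError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance":
            v = np.clip(v, 0.0, 1.0)
        elif self.kind == "illuminant" and v.min() < 0:
            raise DomainError("illuminant spectrum must be non-negative")
        self.values = v

    @property
    def wavelengths(self) -> np.ndarray:
        return WAVELENGTHS


@dataclass
class CmfSet:
    """The three color-matching-function channels xbar, ybar, zbar."""

    xbar: Spectrum
    ybar: Spectrum
    zbar: Spectrum

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            s = getattr(self, name)
            if not isinstance(s, Spectrum):
                s = Spectrum(np.asarray(s), kind="cmf")
                setattr(self, name, s)
            if s.values.min() < 0:
                raise DomainError(f"{name} must be non-negative")

    def as_matrix(self) -> np.ndarray:
        """401 x 3 matrix with columns xbar, ybar, zbar."""
        return np.stack([self.xbar.values, self.ybar.values, self.zbar.values], axis=1)


def _lobe(lam: np.ndarray, mu: float, t1: float, t2: float) -> np.ndarray:
    t = np.where(lam < mu, t1, t2)
    return np.exp(-0.5 * (t * (lam - mu)) ** 2)


def analytic_cmf_table(wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """CIE-1931-2-degree-observer color matching functions, analytic form.

    Synthetic stand-in for the CIE tabulation: the multi-lobe Gaussian fit
    of Wyman, Sloan and Shirley (JCGT 2013), accurate to about a percent of
    peak. Returns an N x 3 array (xbar, ybar, zbar columns).
    """
    lam = np.asarray(wavelengths, dtype=float)
    x = (
        0.362 * _lobe(lam, 442.0, 0.0624, 0.0374)
        + 1.056 * _lobe(lam, 599.8, 0.0264, 0.0323)
        - 0.065 * _lobe(lam, 501.1, 0.0490, 0.0382)
    )
    y = 0.821 * _lobe(lam, 568.8, 0.0213, 0.0247) + 0.286 * _lobe(lam, 530.9, 0.0613, 0.0322)
    z = 1.217 * _lobe(lam, 437.0, 0.0845, 0.0278) + 0.681 * _lobe(lam, 459.0, 0.0385, 0.0725)
    return np.clip(np.stack([x, y, z], axis=1), 0.0, None)


def load_default_cmfs() -> CmfSet:
    """Load the packaged color-matching-function table."""
    path = resources.files("endospect.data") / "cie1931_2deg_analytic.csv"
    raw = np.loadtxt(str(path), delimiter=",", skiprows=1)
    if raw.shape != (N_BANDS, 4):
        raise ShapeError(f"packaged CMF table has shape {raw.shape}")
    return CmfSet(
        Spectrum(raw[:, 1], "cmf"), Spectrum(raw[:, 2], "cmf"), Spectrum(raw[:, 3], "cmf")
    )


def brightness_constant(illuminant: Spectrum, ybar: Spectrum) -> float:
    """Illuminant normalization k = 100 / integral of S(l) ybar(l).

    Rectangle-rule quadrature at the native 1 nm step; k scales the
    tristimulus integrals so a unit reflector has Y = 100.
    """
    integral = float(np.sum(illuminant.values * ybar.values))
    if integral <= 0:
        raise DomainError("degenerate illuminant: S * ybar integrates to zero")
    return 100.0 / integral


def spectrum_to_xyz(
    illuminant: Spectrum, reflectance: Spectrum, cmfs: CmfSet, k: float | None = None
) -> np.ndarray:
    """Tristimulus integrals of one reflectance spectrum (XYZ on the 0-100 scale)."""
    if k is None:
        k = brightness_constant(illuminant, cmfs.ybar)
    weighted = illuminant.values * reflectance.values
    return k * (weighted @ cmfs.as_matrix())


def spectra_to_xyz(
    illuminant: Spectrum, reflectances: np.ndarray, cmfs: CmfSet, k: float | None = None
) -> np.ndarray:
    """Vectorized tristimulus integration for an (n, 401) reflectance stack."""
    R = np.asarray(reflectances, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    if R.shape[-1] != N_BANDS:
        raise ShapeError(f"reflectance stack must have {N_BANDS} bands, got {R.shape}")
    if k is None:
        k = brightness_constant(illuminant, cmfs.ybar)
    return k * ((R * illuminant.values) @ cmfs.as_matrix())


def source_white_point(
    illuminant: Spectrum, cmfs: CmfSet, label: str = "measured-source"
) -> colorcal.WhitePoint:
    """White point of an illuminant: tristimulus of a perfect (R = 1) reflector."""
    xyz = spectrum_to_xyz(illuminant, Spectrum(np.ones(N_BANDS)), cmfs)
    return colorcal.WhitePoint(label, xyz)


@dataclass
class ReflectanceBasis:
    """Mean-centered PCA basis of the training reflectance spectra.

    ``components`` rows are orthonormal, ``scores`` holds the training
    projections (n_patches x p) and ``explained_variance`` is non-increasing.
    """

    mean: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.mean.shape != (N_BANDS,) or self.components.shape[1] != N_BANDS:
            raise ShapeError("basis mean/components must live on the 401-band grid")
        if self.scores.shape[1] != self.components.shape[0]:
            raise ShapeError("scores column count must equal component count")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise DomainError("explained_variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class SpectralTransform:
    """Regression M from expanded corrected-XYZ features to PCA scores."""

    M: np.ndarray
    regressor_spec: Sequence[tuple] = field(default_factory=colorcal.default_regressor_spec)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.regressor_spec = tuple(tuple(int(e) for e in t) for t in self.regressor_spec)
        if self.M.ndim != 2 or self.M.shape[1] != len(self.regressor_spec):
            raise ShapeError(
                f"M shape {self.M.shape} inconsistent with "
                f"{len(self.regressor_spec)} regressor terms"
            )


@dataclass
class HyperspectralCube:
    """H x W x 401 reflectance volume with wavelength metadata."""

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS.copy())
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[2] != N_BANDS:
            raise ShapeError(f"cube must be HxWx{N_BANDS}, got {data.shape}")
        self.data = data
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.shape != (N_BANDS,):
            raise ShapeError("wavelength axis must have 401 entries")

    @property
    def shape(self):
        return self.data.shape


def _spectra_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        R = np.asarray(spectra, dtype=float)
    else:
        R = np.stack([s.values if isinstance(s, Spectrum) else np.asarray(s) for s in spectra])
    if R.ndim != 2 or R.shape[1] != N_BANDS:
        raise ShapeError(f"expected (n, {N_BANDS}) spectra, got {R.shape}")
    return R


def fit_reflectance_basis(spectra, n_components: int = 12) -> ReflectanceBasis:
    """PCA of the training reflectance spectra (top ``n_components`` eigenvectors)."""
    R = _spectra_matrix(spectra)
    n = R.shape[0]
    if not 2 <= n_components <= n - 1:
        raise DomainError(
            f"n_components must lie in [2, {n - 1}] for {n} training spectra, "
            f"got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(R)
    return ReflectanceBasis(
        mean=pca.mean_,
        components=pca.components_,
        scores=scores,
        explained_variance=pca.explained_variance_,
    )


def fit_spectral_transform(
    xyz_correct: np.ndarray, basis: ReflectanceBasis, regressor_spec=None
) -> SpectralTransform:
    """Least-squares fit of PCA scores on polynomially expanded corrected XYZ."""
    if regressor_spec is None:
        regressor_spec = colorcal.default_regressor_spec()
    xyz = np.asarray(xyz_correct, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ShapeError(f"xyz_correct must be (n, 3), got {xyz.shape}")
    if xyz.shape[0] != basis.scores.shape[0]:
        raise ShapeError(
            f"patch count mismatch: {xyz.shape[0]} XYZ rows vs "
            f"{basis.scores.shape[0]} training scores"
        )
    feats = expand_regressors(xyz, regressor_spec)  # (n, m)
    M = (np.linalg.pinv(feats, rcond=1e-12) @ basis.scores).T  # (p, m)
    return SpectralTransform(M=M, regressor_spec=regressor_spec)


def reconstruct_spectra(
    xyz: np.ndarray, basis: ReflectanceBasis, transform: SpectralTransform
) -> np.ndarray:
    """Reflectance spectra for corrected XYZ rows: mean + components' scores, clipped."""
    arr = np.asarray(xyz, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    feats = expand_regressors(arr, transform.regressor_spec)
    scores = feats @ transform.M.T
    R = scores @ basis.components + basis.mean
    R = np.clip(R, 0.0, 1.0)
    return R[0] if squeeze else R


def reconstruct_spectrum(
    xyz, basis: ReflectanceBasis, transform: SpectralTransform
) -> Spectrum:
    """Single-triple convenience wrapper around :func:`reconstruct_spectra`."""
    return Spectrum(reconstruct_spectra(np.asarray(xyz, dtype=float), basis, transform))


def image_to_cube(
    image,
    calib: CameraCalibration,
    basis: ReflectanceBasis,
    transform: SpectralTransform,
    chunk_size: int = 65536,
) -> HyperspectralCube:
    """Per-pixel sRGB -> corrected XYZ -> reflectance spectrum, as a float32 cube.

    The pixel stream is processed in chunks to bound peak memory; the
    result is identical to applying the per-pixel chain individually.
    """
    if calib.C is None:
        raise StateError("camera calibration is unfitted (C is None)")
    if basis is None or transform is None:
        raise StateError("reflectance basis / spectral transform are unfitted")
    px = colorcal._as_float_rgb(image)
    if px.ndim != 3:
        raise ShapeError(f"expected an HxWx3 image, got shape {px.shape}")
    H, W = px.shape[:2]
    flat = px.reshape(-1, 3)
    out = np.empty((flat.shape[0], N_BANDS), dtype=np.float32)
    for start in range(0, flat.shape[0], chunk_size):
        stop = min(start + chunk_size, flat.shape[0])
        xyz = colorcal.srgb_to_xyz(flat[start:stop], calib)
        xyz_c = colorcal.apply_correction(xyz, calib)
        out[start:stop] = reconstruct_spectra(xyz_c, basis, transform).astype(np.float32)
    return HyperspectralCube(
        data=out.reshape(H, W, N_BANDS),
        provenance={"source_shape": (H, W)},
    )


def spectra_rmse_report(simulated, measured):
    """Per-patch RMSE between simulated and measured reflectance sets, plus the mean.

    Returns ``(per_patch, mean)`` with per-patch values on the [0, 1]
    reflectance scale.
    """
    S = _spectra_matrix(simulated)
    R = _spectra_matrix(measured)
    if S.shape != R.shape:
        raise ShapeError(f"set shapes differ: {S.shape} vs {R.shape}")
    per_patch = np.sqrt(np.mean((S - R) ** 2, axis=1))
    return per_patch, float(per_patch.mean())
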