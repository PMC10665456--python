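"""Estimator surface: spectral reconstruction and narrow-band composition.

:class:`SpectralReconstructor` is the core fit/transform object. Fitting
consumes the 24 matched (camera sRGB, spectrometer reflectance) checker
patches and derives, in order: the source white point and normalization
constant k, the chromatic adaptation matrix, the polynomial XYZ correction
C, the PCA reflectance basis, and the score regression M. Transforming
then turns any sRGB frame into an H x W x 401 reflectance cube. The fit
also records the quality-control quantities reported for real calibration
hardware: pooled endoscope-XYZ RMSE, per-patch spectral RMSE, and
per-patch CIEDE2000 between simulated and measured patch colors.

:class:`HnbiComposer` is the stateless cube -> narrow-band-composite
transformer. Both follow scikit-learn conventions (``get_params`` /
``set_params``, trailing-underscore fitted attributes) and compose with
sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import colorcal, metrics, nbisim, spectral
from .colorcal import CameraCalibration, D65
from .errors import ShapeError, StateError
from .spectral import HyperspectralCube, Spectrum

__all__ = ["SpectralReconstructor", "HnbiComposer"]


class SpectralReconstructor(TransformerMixin, BaseEstimator):
    """Reconstruct visible-range reflectance spectra from camera sRGB.

    Parameters
    ----------
    illuminant : Spectrum or None
        Light-source spectrum of the calibration scene. ``None`` selects a
        flat (equal-energy) spectrum.
    cmfs : CmfSet or None
        Color-matching functions; ``None`` loads the packaged table.
    n_components : int, default 12
        Principal components retained from the 24 training spectra (2-23).
    regressor_degree : int, default 3
        Total degree of the monomial expansion used for the XYZ correction.
    score_features : {"polynomial", "linear"}, default "polynomial"
        Whether the score regression M reuses the polynomial expansion or
        only the linear XYZ terms.
    adaptation : {"bradford", "von_kries", "xyz_scaling"}, default "bradford"
        Chromatic adaptation method from the sRGB D65 white to the source.
    rgb_to_xyz_matrix : array or None
        Override for the linear-RGB -> XYZ primaries matrix T.
    chunk_size : int, default 65536
        Pixels processed per block when transforming images.

    Attributes (after ``fit``)
    ----------
    calibration_ : CameraCalibration        fitted T, M_A, C
    basis_ : ReflectanceBasis               PCA mean/components/scores
    transform_ : SpectralTransform          score regression M
    source_white_ : WhitePoint              white of the calibration source
    k_ : float                              illuminant normalization constant
    xyz_spectrum_, xyz_endoscope_, xyz_correct_ : (n, 3) arrays
    xyz_rmse_ : float                       pooled RMSE of corrected vs measured XYZ
    patch_rmse_, mean_rmse_ : QC spectral reconstruction errors
    patch_delta_e_, mean_delta_e_ : QC CIEDE2000 of simulated vs measured patches
    """

    def __init__(
        self,
        illuminant=None,
        cmfs=None,
        n_components: int = 12,
        regressor_degree: int = 3,
        score_features: str = "polynomial",
        adaptation: str = "bradford",
        rgb_to_xyz_matrix=None,
        chunk_size: int = 65536,
    ):
        self.illuminant = illuminant
        self.cmfs = cmfs
        self.n_components = n_components
        self.regressor_degree = regressor_degree
        self.score_features = score_features
        self.adaptation = adaptation
        self.rgb_to_xyz_matrix = rgb_to_xyz_matrix
        self.chunk_size = chunk_size

    # -- fitting -----------------------------------------------------------

    def _resolved_inputs(self):
        illuminant = self.illuminant
        if illuminant is None:
            illuminant = spectral.Spectrum(np.ones(spectral.N_BANDS), "illuminant")
        cmfs = self.cmfs if self.cmfs is not None else spectral.load_default_cmfs()
        return illuminant, cmfs

    def fit(self, X, y):
        """Fit all calibration artifacts from matched checker measurements.

        X : (n_patches, 3) camera sRGB triples in [0, 1] (or 0-255 uint8)
        y : list of Spectrum / (n_patches, 401) measured reflectance spectra
        """
        rgb = colorcal._as_float_rgb(np.asarray(X))
        if rgb.ndim != 2:
            raise ShapeError(f"X must be (n_patches, 3), got {np.asarray(X).shape}")
        R = spectral._spectra_matrix(y)
        if R.shape[0] != rgb.shape[0]:
            raise ShapeError(
                f"{rgb.shape[0]} sRGB rows but {R.shape[0]} reflectance spectra"
            )
        illuminant, cmfs = self._resolved_inputs()
        spec = colorcal.default_regressor_spec(self.regressor_degree)

        self.k_ = spectral.brightness_constant(illuminant, cmfs.ybar)
        self.source_white_ = spectral.source_white_point(illuminant, cmfs)
        M_A = colorcal.adaptation_matrix(D65, self.source_white_, method=self.adaptation)
        T = (
            np.asarray(self.rgb_to_xyz_matrix, dtype=float)
            if self.rgb_to_xyz_matrix is not None
            else colorcal.SRGB_TO_XYZ
        )
        calib = CameraCalibration(T=T, M_A=M_A, regressor_spec=spec)

        self.xyz_spectrum_ = spectral.spectra_to_xyz(illuminant, R, cmfs, self.k_)
        self.xyz_endoscope_ = colorcal.srgb_to_xyz(rgb, calib)
        V = colorcal.expand_regressors(self.xyz_endoscope_, spec).T
        calib.C = colorcal.fit_correction_matrix(self.xyz_spectrum_.T, V)
        self.calibration_ = calib
        self.xyz_correct_ = colorcal.apply_correction(self.xyz_endoscope_, calib)
        self.xyz_rmse_ = colorcal.rmse(self.xyz_correct_, self.xyz_spectrum_)

        self.basis_ = spectral.fit_reflectance_basis(R, self.n_components)
        score_spec = (
            spec
            if self.score_features == "polynomial"
            else colorcal.default_regressor_spec(1, include_constant=False)
        )
        self.transform_ = spectral.fit_spectral_transform(
            self.xyz_correct_, self.basis_, score_spec
        )

        simulated = spectral.reconstruct_spectra(self.xyz_correct_, self.basis_, self.transform_)
        self.patch_rmse_, self.mean_rmse_ = spectral.spectra_rmse_report(simulated, R)
        sim_xyz = spectral.spectra_to_xyz(illuminant, simulated, cmfs, self.k_)
        lab_sim = metrics.xyz_to_lab(sim_xyz, self.source_white_)
        lab_meas = metrics.xyz_to_lab(self.xyz_spectrum_, self.source_white_)
        self.patch_delta_e_ = np.asarray(metrics.ciede2000(lab_sim, lab_meas))
        self.mean_delta_e_ = float(self.patch_delta_e_.mean())
        self.n_features_in_ = 3
        return self

    # -- application -------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "calibration_"):
            raise StateError("SpectralReconstructor is not fitted yet")

    def transform(self, X):
        """sRGB to reflectance. (n, 3) triples -> (n, 401); HxWx3 image -> cube."""
        self._check_fitted()
        arr = np.asarray(X)
        if arr.ndim == 3:
            cube = spectral.image_to_cube(
                arr, self.calibration_, self.basis_, self.transform_, self.chunk_size
            )
            return cube
        rgb = colorcal._as_float_rgb(arr)
        xyz = colorcal.srgb_to_xyz(rgb, self.calibration_)
        xyz_c = colorcal.apply_correction(xyz, self.calibration_)
        return spectral.reconstruct_spectra(xyz_c, self.basis_, self.transform_)

    def reconstruct_from_xyz(self, xyz) -> np.ndarray:
        """Reflectance spectra for already-corrected XYZ rows."""
        self._check_fitted()
        return spectral.reconstruct_spectra(xyz, self.basis_, self.transform_)

    def qc_report(self) -> dict:
        """Calibration quality-control quantities as a JSON-friendly dict."""
        self._check_fitted()
        return {
            "xyz_rmse": self.xyz_rmse_,
            "patch_rmse": self.patch_rmse_.tolist(),
            "mean_rmse": self.mean_rmse_,
            "patch_delta_e": self.patch_delta_e_.tolist(),
            "mean_delta_e": self.mean_delta_e_,
            "n_components": self.basis_.n_components,
        }


class HnbiComposer(TransformerMixin, BaseEstimator):
    """Compose narrow-band pseudo-color images from reflectance cubes.

    Stateless: ``fit`` records nothing beyond validation. ``transform``
    accepts a cube (or list of cubes) and returns the display composite.
    """

    def __init__(self, wavelengths=(415.0, 540.0), mapping=None, percentiles=(1.0, 99.0)):
        self.wavelengths = wavelengths
        self.mapping = mapping
        self.percentiles = percentiles

    def fit(self, X=None, y=None):
        nbisim.BandSelection(tuple(self.wavelengths))  # validates
        self.is_fitted_ = True
        return self

    def _compose_one(self, cube: HyperspectralCube) -> nbisim.HnbiImage:
        selection = nbisim.BandSelection(tuple(self.wavelengths))
        planes = nbisim.extract_bands(cube, selection)
        by_wavelength = dict(zip(selection.wavelengths, planes))
        return nbisim.compose_hnbi(
            by_wavelength[415.0] if 415.0 in by_wavelength else planes[0],
            by_wavelength[540.0] if 540.0 in by_wavelength else planes[-1],
            mapping=self.mapping,
            percentiles=tuple(self.percentiles),
        )

    def transform(self, X):
        if isinstance(X, HyperspectralCube):
            return self._compose_one(X)
        return [self._compose_one(c) for c in X]
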