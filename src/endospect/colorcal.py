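"""Camera-side colorimetry.

Converts the endoscope's rendered sRGB values into CIE XYZ tristimulus
values under the measured light source, and fits the polynomial
correction that maps camera XYZ onto spectrometer-derived XYZ.

The chain is::

    sRGB (0-1) --inverse gamma--> linear RGB --T--> XYZ(D65) --M_A--> XYZ(source) x 100

followed by a multiple-regression correction ``XYZ_correct = C @ V(XYZ)``
where ``V`` expands XYZ into a configurable monomial basis (by default all
monomials of total degree 1..3 plus a constant, 20 terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, ShapeError, StateError

__all__ = [
    "SRGB_TO_XYZ",
    "D65_WHITE",
    "D50_WHITE",
    "WhitePoint",
    "D65",
    "SrgbImage",
    "CameraCalibration",
    "linearize_srgb",
    "encode_srgb",
    "srgb_to_xyz",
    "adaptation_matrix",
    "default_regressor_spec",
    "expand_regressors",
    "fit_correction_matrix",
    "apply_correction",
    "rmse",
]

# IEC 61966-2-1 sRGB primaries, D65 white, row order X/Y/Z.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

D65_WHITE = np.array([95.047, 100.0, 108.883])
D50_WHITE = np.array([96.4212, 100.0, 82.5188])

# Cone-response matrices for chromatic adaptation.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_VON_KRIES = np.array(
    [
        [0.40024, 0.70760, -0.08081],
        [-0.22630, 1.16532, 0.04570],
        [0.0, 0.0, 0.91822],
    ]
)
_CONE_MATRICES = {
    "bradford": _BRADFORD,
    "von_kries": _VON_KRIES,
    "xyz_scaling": np.eye(3),
}

_SRGB_GAMMA_THRESHOLD = 0.04045
_SRGB_LINEAR_THRESHOLD = 0.0031308


@dataclass(frozen=True)
class WhitePoint:
    """A reference white, normalized so Y = 100."""

    label: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,):
            raise ShapeError(f"white point must be a 3-vector, got shape {xyz.shape}")
        if not np.all(np.isfinite(xyz)):
            raise DomainError(f"white point contains non-finite values: {xyz}")
        if abs(xyz[1] - 100.0) > 1e-6:
            raise DomainError(f"white point Y must equal 100, got {xyz[1]!r}")
        if np.any(xyz <= 0):
            raise DomainError(f"degenerate white point (non-positive component): {xyz}")
        object.__setattr__(self, "xyz", xyz)


D65 = WhitePoint("D65", D65_WHITE)
D50 = WhitePoint("D50", D50_WHITE)


@dataclass
class SrgbImage:
    """An sRGB-encoded image, either 8-bit (0-255) or normalized floats (0-1)."""

    pixels: np.ndarray
    encoding: str = "8bit"  # "8bit" | "float"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(f"expected HxWx3 pixels, got shape {px.shape}")
        if self.encoding not in ("8bit", "float"):
            raise DomainError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "8bit":
            if px.min() < 0 or px.max() > 255:
                raise DomainError("8-bit image values must lie in [0, 255]")
        else:
            if px.min() < 0 or px.max() > 1:
                raise DomainError("normalized image values must lie in [0, 1]")
        self.pixels = px

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SrgbImage":
        arr = np.asarray(arr)
        if arr.dtype == np.uint8:
            return cls(arr, "8bit")
        return cls(arr, "float")

    def as_float(self) -> np.ndarray:
        """Pixels as floats on the 0-1 scale (8-bit images divided by 255)."""
        if self.encoding == "8bit":
            return self.pixels.astype(np.float64) / 255.0
        return self.pixels.astype(np.float64)

    @property
    def shape(self):
        return self.pixels.shape


def _as_float_rgb(rgb) -> np.ndarray:
    if isinstance(rgb, SrgbImage):
        return rgb.as_float()
    arr = np.asarray(rgb)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    if arr.shape[-1] != 3:
        raise ShapeError(f"expected trailing RGB axis of length 3, got shape {arr.shape}")
    return arr


def linearize_srgb(value):
    """Invert the sRGB transfer function (gamma decoding).

    Piecewise IEC 61966-2-1: ``v / 12.92`` below 0.04045, else
    ``((v + 0.055) / 1.055) ** 2.4``. Accepts scalars or arrays in [0, 1].
    """
    arr = np.asarray(value, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        bad = arr.flat[int(np.argmax((arr < 0) | (arr > 1)))]
        raise DomainError(f"sRGB value {bad!r} outside [0, 1]")
    out = np.where(
        arr <= _SRGB_GAMMA_THRESHOLD,
        arr / 12.92,
        ((arr + 0.055) / 1.055) ** 2.4,
    )
    return out if isinstance(value, np.ndarray) else float(out) if np.isscalar(value) else out


def encode_srgb(linear):
    """Apply the sRGB transfer function (gamma encoding) to linear values in [0, 1]."""
    arr = np.asarray(linear, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        bad = arr.flat[int(np.argmax((arr < 0) | (arr > 1)))]
        raise DomainError(f"linear value {bad!r} outside [0, 1]")
    out = np.where(
        arr <= _SRGB_LINEAR_THRESHOLD,
        arr * 12.92,
        1.055 * np.power(arr, 1.0 / 2.4, where=arr > 0, out=np.zeros_like(arr)) - 0.055,
    )
    return out if isinstance(linear, np.ndarray) else float(out) if np.isscalar(linear) else out


def adaptation_matrix(source: WhitePoint, dest: WhitePoint, method: str = "bradford") -> np.ndarray:
    """Chromatic adaptation matrix mapping XYZ under ``source`` to XYZ under ``dest``.

    The default is the Bradford transform: project both whites into cone
    space, scale each cone channel by the ratio of the destination to the
    source response, and project back.
    """
    try:
        cone = _CONE_MATRICES[method]
    except KeyError:
        raise DomainError(
            f"unknown adaptation method {method!r}; choose from {sorted(_CONE_MATRICES)}"
        ) from None
    s = cone @ source.xyz
    d = cone @ dest.xyz
    if np.any(s <= 0) or np.any(d <= 0):
        raise DomainError("degenerate white point: non-positive cone response")
    return np.linalg.inv(cone) @ np.diag(d / s) @ cone


def default_regressor_spec(degree: int = 3, include_constant: bool = True):
    """Monomial exponent triples (a, b, c) for the polynomial regressor matrix V.

    Contains every monomial ``X^a Y^b Z^c`` with ``1 <= a+b+c <= degree``,
    optionally preceded by a constant term. ``degree=3`` with a constant
    yields 20 terms, which keeps the fit determined by 24 patches.
    """
    if degree < 1:
        raise DomainError(f"degree must be >= 1, got {degree}")
    terms = [(0, 0, 0)] if include_constant else []
    for total in range(1, degree + 1):
        for a in range(total, -1, -1):
            for b in range(total - a, -1, -1):
                terms.append((a, b, total - a - b))
    return tuple(terms)


@dataclass
class CameraCalibration:
    """Everything needed to map camera sRGB to corrected XYZ.

    T is the linear-RGB to XYZ primaries matrix (standard sRGB by default,
    never estimated from data), M_A the chromatic adaptation matrix from the
    D65 white of the sRGB gamut to the measured source white, and C the
    fitted 3 x n polynomial correction matrix over ``regressor_spec``.
    """

    T: np.ndarray = field(default_factory=lambda: SRGB_TO_XYZ.copy())
    M_A: np.ndarray = field(default_factory=lambda: np.eye(3))
    regressor_spec: Sequence[tuple] = field(default_factory=default_regressor_spec)
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.M_A = np.asarray(self.M_A, dtype=float)
        if self.T.shape != (3, 3) or self.M_A.shape != (3, 3):
            raise ShapeError("T and M_A must be 3x3 matrices")
        if abs(np.linalg.det(self.T)) < 1e-12:
            raise DomainError("primaries matrix T is singular")
        self.regressor_spec = tuple(tuple(int(e) for e in t) for t in self.regressor_spec)
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)
            if self.C.shape != (3, len(self.regressor_spec)):
                raise ShapeError(
                    f"C shape {self.C.shape} inconsistent with "
                    f"{len(self.regressor_spec)} regressor terms"
                )


def srgb_to_xyz(rgb, calib: CameraCalibration | None = None) -> np.ndarray:
    """Convert sRGB (scalars in [0, 1], trailing axis RGB) to XYZ on the 0-100 scale.

    Computes ``M_A @ T @ linearize(rgb) * 100``; with the default
    calibration (identity M_A, standard sRGB T) white maps to D65.
    """
    if calib is None:
        calib = CameraCalibration()
    arr = _as_float_rgb(rgb)
    lin = linearize_srgb(arr)
    return lin @ (calib.M_A @ calib.T).T * 100.0


def expand_regressors(xyz, spec) -> np.ndarray:
    """Evaluate each monomial ``X^a Y^b Z^c`` of ``spec`` at XYZ (trailing axis 3)."""
    spec = tuple(tuple(t) for t in spec)
    if not spec:
        raise DomainError("regressor spec is empty")
    for lin in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        if lin not in spec:
            raise DomainError(f"regressor spec must contain the linear term {lin}")
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ShapeError(f"expected trailing XYZ axis of length 3, got shape {arr.shape}")
    X, Y, Z = arr[..., 0], arr[..., 1], arr[..., 2]
    cols = [(X ** a) * (Y ** b) * (Z ** c) for a, b, c in spec]
    return np.stack(cols, axis=-1)


def fit_correction_matrix(xyz_spectrum: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Least-squares correction matrix ``C = XYZ_spectrum @ pinv(V)``.

    ``xyz_spectrum`` is 3 x N (patches in columns) and ``V`` is n x N.
    The pseudoinverse (SVD, relative cutoff 1e-12) gives the minimum-norm
    solution on rank deficiency.
    """
    xyz_spectrum = np.asarray(xyz_spectrum, dtype=float)
    V = np.asarray(V, dtype=float)
    if xyz_spectrum.ndim != 2 or xyz_spectrum.shape[0] != 3:
        raise ShapeError(f"xyz_spectrum must be 3xN, got {xyz_spectrum.shape}")
    if V.ndim != 2 or V.shape[1] != xyz_spectrum.shape[1]:
        raise ShapeError(
            f"V has {V.shape[1] if V.ndim == 2 else '?'} columns, "
            f"expected {xyz_spectrum.shape[1]}"
        )
    return xyz_spectrum @ np.linalg.pinv(V, rcond=1e-12)


def apply_correction(xyz, calib: CameraCalibration) -> np.ndarray:
    """Apply the fitted polynomial correction: ``C @ V(xyz)`` (trailing axis XYZ)."""
    if calib.C is None:
        raise StateError("correction matrix C has not been fitted")
    V = expand_regressors(xyz, calib.regressor_spec)
    return V @ calib.C.T


def rmse(a, b) -> float:
    """Root-mean-square difference over all elements of two equal-size arrays."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ShapeError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise DomainError("rmse of empty arrays is undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)))
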