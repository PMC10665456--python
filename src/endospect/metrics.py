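"""Image-quality metrics: CIEDE2000, Shannon entropy, SSIM, summary tables.

CIEDE2000 is implemented in full (a' chroma rescaling, lightness/chroma/hue
weighting functions, hue-rotation term R_T) following the standard
formulation; abbreviated statements of the formula that keep only the
top-level quadratic combination are not computable on their own.

Entropy is the non-negative convention H = -sum p log2 p over a 256-bin
grayscale histogram, bounded by [0, 8] bits for 8-bit sources. SSIM uses
the field-standard 11x11 Gaussian window (sigma = 1.5); the literal
single-window global form is available via ``mode="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from . import colorcal
from .colorcal import D65, SrgbImage, WhitePoint
from .errors import DomainError, PairingError, ShapeError

__all__ = [
    "LabColor",
    "Ciede2000Params",
    "RegionMasks",
    "SummaryStats",
    "SsimParams",
    "rgb_to_lab",
    "xyz_to_lab",
    "ciede2000",
    "region_color_difference",
    "shannon_entropy",
    "ssim",
    "summarize",
    "evaluate_batch",
]

# ITU-R BT.601 luma weights for grayscale reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color: L in [0, 100] for in-gamut inputs, a/b unbounded."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class Ciede2000Params:
    """Parametric weighting factors kL, kC, kH of the color-difference formula."""

    kL: float = 1.0
    kC: float = 1.0
    kH: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kL, self.kC, self.kH) <= 0:
            raise DomainError("kL, kC, kH must all be strictly positive")


@dataclass
class RegionMasks:
    """Disjoint boolean masks delineating vessel and background regions."""

    vessel: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vessel, dtype=bool)
        b = np.asarray(self.background, dtype=bool)
        if v.shape != b.shape:
            raise ShapeError(f"mask shapes differ: {v.shape} vs {b.shape}")
        if not v.any() or not b.any():
            raise DomainError("vessel and background masks must both be non-empty")
        if np.any(v & b):
            raise DomainError("vessel and background masks must be disjoint")
        self.vessel, self.background = v, b


@dataclass(frozen=True)
class SummaryStats:
    """Min / average / max of a metric over an image set."""

    minimum: float
    average: float
    maximum: float
    n: int


@dataclass(frozen=True)
class SsimParams:
    """SSIM window and stability constants (defaults match the common usage)."""

    win_size: int = 11
    sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    data_range: float = 255.0

    @property
    def C1(self) -> float:
        return (self.K1 * self.data_range) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.data_range) ** 2


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white: WhitePoint = D65) -> np.ndarray:
    """XYZ (0-100 scale, trailing axis 3) to CIELAB under the given reference white."""
    arr = np.asarray(xyz, dtype=float)
    f = _lab_f(arr / white.xyz)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(rgb, white: WhitePoint = D65) -> np.ndarray:
    """sRGB in [0, 1] (trailing axis 3) to CIELAB via the standard primaries matrix."""
    xyz = colorcal.srgb_to_xyz(rgb)
    return xyz_to_lab(xyz, white)


def _as_lab_array(c) -> np.ndarray:
    if isinstance(c, LabColor):
        return c.as_array()
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1] != 3:
        raise ShapeError(f"expected trailing Lab axis of length 3, got {arr.shape}")
    return arr


def ciede2000(c1, c2, params: Ciede2000Params = Ciede2000Params()) -> np.ndarray | float:
    """The complete CIEDE2000 color difference between two Lab colors.

    Accepts :class:`LabColor` instances or arrays with a trailing axis of 3
    (broadcast over leading axes). Symmetric in its arguments for the
    default kL = kC = kH = 1 and zero iff the colors coincide.
    """
    lab1 = _as_lab_array(c1)
    lab2 = _as_lab_array(c2)
    scalar = lab1.ndim == 1 and lab2.ndim == 1
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((b1 == 0) & (a1p == 0), 0.0, h1p)
    h2p = np.where((b2 == 0) & (a2p == 0), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum, 0.5 * (hsum + 360.0))
    hbp = np.where((habs > 180.0) & (hsum >= 360.0), 0.5 * (hsum - 360.0), hbp)
    hbp = np.where(C1p * C2p == 0, hsum, hbp)  # convention: degenerate chroma

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (params.kL * SL)
    tC = dCp / (params.kC * SC)
    tH = dHp / (params.kH * SH)
    dE = np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
    return float(dE) if scalar else dE


def _as_float_image(image) -> np.ndarray:
    """Any accepted image form to float on the 0-255 display scale."""
    if isinstance(image, SrgbImage):
        return image.as_float() * 255.0
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    arr = arr.astype(np.float64)
    if arr.size and arr.max() <= 1.0 and arr.min() >= 0.0:
        return arr * 255.0
    return arr


def _to_gray(image) -> np.ndarray:
    """Grayscale plane on the 0-255 scale using BT.601 luma weights."""
    arr = _as_float_image(image)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ShapeError(f"expected 3 channels, got shape {arr.shape}")
        return arr @ LUMA_WEIGHTS
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2-D or HxWx3 image, got shape {arr.shape}")
    return arr


def region_color_difference(
    image,
    masks: RegionMasks,
    white: WhitePoint = D65,
    params: Ciede2000Params = Ciede2000Params(),
) -> float:
    """CIEDE2000 between the mean vessel color and the mean background color.

    Pixel colors are averaged in Lab within each mask before the single
    color-difference evaluation, so the result is invariant to permuting
    pixels inside a region.
    """
    px = _as_float_image(image) / 255.0
    if px.ndim != 3 or px.shape[2] != 3:
        raise ShapeError(f"expected an HxWx3 image, got {px.shape}")
    if masks.vessel.shape != px.shape[:2]:
        raise ShapeError(
            f"mask shape {masks.vessel.shape} does not match image {px.shape[:2]}"
        )
    lab = rgb_to_lab(px, white)
    mean_vessel = lab[masks.vessel].mean(axis=0)
    mean_background = lab[masks.background].mean(axis=0)
    return float(ciede2000(mean_vessel, mean_background, params))


def shannon_entropy(image) -> float:
    """Shannon entropy in bits of the 256-bin grayscale histogram.

    H = -sum p log2 p with 0 log 0 = 0; ranges over [0, 8] for 8-bit
    sources and is invariant under spatial permutation of pixels.
    """
    gray = _to_gray(image)
    if gray.size == 0:
        raise DomainError("entropy of an empty image is undefined")
    counts, _ = np.histogram(gray, bins=256, range=(0.0, 256.0))
    p = counts[counts > 0] / gray.size
    return float(-np.sum(p * np.log2(p)))


def ssim(img1, img2, params: SsimParams = SsimParams(), mode: str = "windowed") -> float:
    """Structural similarity between two images (grayscale luma), in [-1, 1].

    ``mode="windowed"`` averages the local SSIM map computed over a
    Gaussian-weighted window; ``mode="global"`` evaluates the similarity
    formula once over whole-image statistics.
    """
    g1 = _to_gray(img1)
    g2 = _to_gray(img2)
    if g1.shape != g2.shape:
        raise ShapeError(f"image shapes differ: {g1.shape} vs {g2.shape}")
    if mode == "windowed":
        return float(
            structural_similarity(
                g1,
                g2,
                win_size=params.win_size,
                gaussian_weights=True,
                sigma=params.sigma,
                use_sample_covariance=False,
                K1=params.K1,
                K2=params.K2,
                data_range=params.data_range,
            )
        )
    if mode == "global":
        mu1, mu2 = g1.mean(), g2.mean()
        var1, var2 = g1.var(), g2.var()
        cov = np.mean((g1 - mu1) * (g2 - mu2))
        C1, C2 = params.C1, params.C2
        return float(
            ((2 * mu1 * mu2 + C1) * (2 * cov + C2))
            / ((mu1**2 + mu2**2 + C1) * (var1 + var2 + C2))
        )
    raise DomainError(f"unknown SSIM mode {mode!r}")


def summarize(values: Sequence[float]) -> SummaryStats:
    """Exact min, arithmetic mean, and max of a metric value list."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty value list")
    import math

    # fsum keeps the mean exactly invariant under input permutation
    return SummaryStats(
        minimum=float(arr.min()),
        average=math.fsum(arr) / arr.size,
        maximum=float(arr.max()),
        n=int(arr.size),
    )


def evaluate_batch(
    image_sets: Mapping[str, Sequence],
    masks: Mapping[str, Sequence[RegionMasks]] | None = None,
    ssim_pairs: Mapping[str, tuple] | None = None,
    metrics: Sequence[str] = ("ciede2000", "entropy", "ssim"),
    white: WhitePoint = D65,
) -> pd.DataFrame:
    """Min/avg/max summary table per labeled image set, per metric.

    ``image_sets`` maps label -> list of images. Region color difference
    requires ``masks[label]`` aligned with the image list; SSIM requires
    ``ssim_pairs[label] = (set_a, set_b)`` of equal-length paired sets.
    Returns a tidy frame with columns label, metric, n, min, avg, max.
    """
    rows = []
    for label, images in image_sets.items():
        if "ciede2000" in metrics and masks is not None and label in masks:
            mask_list = masks[label]
            if len(mask_list) != len(images):
                raise PairingError(
                    f"{label}: {len(images)} images but {len(mask_list)} masks"
                )
            vals = [
                region_color_difference(im, mk, white) for im, mk in zip(images, mask_list)
            ]
            rows.append((label, "ciede2000", summarize(vals)))
        if "entropy" in metrics:
            vals = [shannon_entropy(im) for im in images]
            rows.append((label, "entropy", summarize(vals)))
    if "ssim" in metrics and ssim_pairs:
        for label, (set_a, set_b) in ssim_pairs.items():
            if len(set_a) != len(set_b):
                raise PairingError(
                    f"{label}: SSIM sets have lengths {len(set_a)} and {len(set_b)}"
                )
            vals = [ssim(a, b) for a, b in zip(set_a, set_b)]
            rows.append((label, "ssim", summarize(vals)))
    return pd.DataFrame(
        [
            {
                "label": label,
                "metric": metric,
                "n": s.n,
                "min": s.minimum,
                "avg": s.average,
                "max": s.maximum,
            }
            for label, metric, s in rows
        ]
    )
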