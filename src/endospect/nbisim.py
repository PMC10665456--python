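"""Narrow-band image simulation from reconstructed reflectance cubes.

Hemoglobin absorbs strongly near 415 nm and again near 540 nm, so the
415 nm reflectance plane darkens superficial mucosal microvessels while
the 540 nm plane carries submucosal vessel contrast. Selecting those two
planes from the cube and mapping them onto display channels emulates the
look of narrow-band endoscopy: by default the 540 nm plane feeds the red
channel and the 415 nm plane feeds green and blue, rendering microvessels
brown and deeper vessels blue/cyan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.transform import resize as _sk_resize

from .colorcal import SrgbImage, encode_srgb
from .errors import DomainError, EmptyContentError, ShapeError
from .spectral import HyperspectralCube, N_BANDS, WAVELENGTHS

__all__ = [
    "BandSelection",
    "HnbiImage",
    "DEFAULT_CHANNEL_MAP",
    "preprocess",
    "resolve_band_index",
    "extract_bands",
    "compose_hnbi",
]

# Display channel -> source wavelength (nm).
DEFAULT_CHANNEL_MAP: Mapping[str, float] = {"R": 540.0, "G": 415.0, "B": 415.0}


@dataclass
class BandSelection:
    """Wavelengths to extract from a cube, resolved to band indices."""

    wavelengths: tuple = (415.0, 540.0)

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        for w in self.wavelengths:
            resolve_band_index(w)  # validates range

    @property
    def indices(self) -> tuple:
        return tuple(resolve_band_index(w) for w in self.wavelengths)


@dataclass
class HnbiImage:
    """Display-encoded narrow-band composite plus its channel/band mapping record."""

    pixels: np.ndarray
    mapping: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))


def _content_box(gray: np.ndarray, threshold: float) -> tuple:
    """Bounding box (top, bottom, left, right) of non-border content.

    A row/column counts as border when its mean intensity (0-255 scale)
    falls below ``threshold``; trimming proceeds inward from each edge.
    """
    row_means = gray.mean(axis=1)
    col_means = gray.mean(axis=0)
    rows = np.nonzero(row_means >= threshold)[0]
    cols = np.nonzero(col_means >= threshold)[0]
    if rows.size == 0 or cols.size == 0:
        raise EmptyContentError("no content remains after black-border trimming")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def preprocess(
    image,
    target_size: int = 380,
    border_threshold: float = 10.0,
    crop: tuple | None = None,
) -> SrgbImage:
    """Trim black borders, apply an optional crop rectangle, resize to a square.

    ``crop`` is an optional (top, bottom, left, right) rectangle, applied
    after border trimming, for removing overlaid patient information.
    Resizing uses bilinear interpolation; an already-borderless image of
    the target size passes through unchanged, making the operation
    idempotent.
    """
    img = image if isinstance(image, SrgbImage) else SrgbImage.from_array(np.asarray(image))
    px = img.pixels
    if px.shape[0] < 32 or px.shape[1] < 32:
        raise DomainError(f"image too small to preprocess: {px.shape[:2]}")
    scale = 1.0 if img.encoding == "8bit" else 255.0
    gray = px.astype(np.float64).mean(axis=2) * scale
    top, bottom, left, right = _content_box(gray, border_threshold)
    content = px[top:bottom, left:right]
    if crop is not None:
        t, b, l, r = crop
        content = content[t:b, l:r]
        if content.size == 0:
            raise EmptyContentError("crop rectangle removed all content")
    if content.shape[0] == target_size and content.shape[1] == target_size:
        return SrgbImage(content, img.encoding)
    out = _sk_resize(
        content.astype(np.float64),
        (target_size, target_size),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    if img.encoding == "8bit":
        out = np.clip(np.rint(out), 0, 255).astype(px.dtype if px.dtype == np.uint8 else np.uint8)
    return SrgbImage(out, img.encoding)


def resolve_band_index(wavelength_nm: float) -> int:
    """Nearest band index on the 380-780 nm, 1 nm grid (380 -> 0, 780 -> 400)."""
    w = float(wavelength_nm)
    if not WAVELENGTHS[0] <= w <= WAVELENGTHS[-1]:
        raise DomainError(f"wavelength {w} nm outside the 380-780 nm grid")
    return int(round(w - WAVELENGTHS[0]))


def extract_bands(cube: HyperspectralCube, selection: BandSelection) -> list:
    """The cube planes named by the selection, in selection order (views, not copies)."""
    return [cube.data[:, :, i] for i in selection.indices]


def _normalize_plane(plane: np.ndarray, p_low: float, p_high: float) -> np.ndarray:
    lo, hi = np.percentile(plane, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(plane, dtype=np.float64)
    return (np.clip(plane, lo, hi) - lo) / (hi - lo)


def compose_hnbi(
    plane_415: np.ndarray,
    plane_540: np.ndarray,
    mapping: Mapping[str, float] | None = None,
    percentiles: tuple = (1.0, 99.0),
) -> HnbiImage:
    """Compose the narrow-band pseudo-color image from the two reflectance planes.

    Each plane is independently normalized between its robust percentiles
    (so the output is invariant to global positive scaling), gamma-encoded
    with the sRGB transfer function, and routed to display channels per
    ``mapping`` (default: 540 nm -> R, 415 nm -> G and B).
    """
    a415 = np.asarray(plane_415, dtype=np.float64)
    a540 = np.asarray(plane_540, dtype=np.float64)
    if a415.shape != a540.shape:
        raise ShapeError(f"plane shapes differ: {a415.shape} vs {a540.shape}")
    if mapping is None:
        mapping = DEFAULT_CHANNEL_MAP
    planes = {415.0: a415, 540.0: a540}
    p_low, p_high = percentiles
    encoded = {
        w: encode_srgb(_normalize_plane(p, p_low, p_high)) for w, p in planes.items()
    }
    out = np.zeros(a415.shape + (3,), dtype=np.float64)
    for ch, idx in (("R", 0), ("G", 1), ("B", 2)):
        w = float(mapping[ch])
        if w not in encoded:
            raise DomainError(f"channel {ch} mapped to {w} nm, which is not an input plane")
        out[:, :, idx] = encoded[w]
    pixels = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return HnbiImage(pixels=pixels, mapping={k: float(v) for k, v in mapping.items()})
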