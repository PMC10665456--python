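"""Synthetic fixtures: checker spectra, illuminants, camera forward model, phantoms.

Clinical endoscopy frames and the physical 24-patch checker are not
distributable, so every pipeline stage is exercised on synthetic stand-ins:

* smooth sum-of-Gaussians reflectance spectra emulating matte color-checker
  patches (optionally confined to a low-dimensional linear span so that
  PCA reconstruction can be exact);
* flat / blackbody / dual-narrowband illuminants (the narrowband pair at
  415 and 540 nm mimics an NBI light source);
* a camera forward model that inverts the calibration chain (tristimulus
  integration, chromatic adaptation to D65, inverse sRGB primaries, gamma
  encoding) with optional linear XYZ distortion and multiplicative sensor
  noise, producing matched (sRGB, spectrum) calibration pairs;
* vessel phantoms: curvilinear strokes with a hemoglobin-like 415/540 nm
  absorption dip on a pink mucosa background, with exact region masks.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from . import colorcal
from .colorcal import D65, SRGB_TO_XYZ, adaptation_matrix, encode_srgb
from .errors import DomainError
from .metrics import RegionMasks
from .spectral import (
    CmfSet,
    N_BANDS,
    Spectrum,
    WAVELENGTHS,
    source_white_point,
    spectra_to_xyz,
)

__all__ = [
    "SyntheticCheckerConfig",
    "PhantomScene",
    "generate_reflectance_set",
    "generate_illuminant",
    "forward_camera",
    "generate_phantom",
    "mucosa_reflectance",
    "vessel_reflectance",
]


@dataclass(frozen=True)
class SyntheticCheckerConfig:
    """Parameters of the synthetic color-checker spectrum generator.

    Each patch spectrum is a baseline plus up to ``n_gaussians`` Gaussian
    bumps, clipped to [0.02, 0.98]. When ``rank`` is set, that many
    endmember spectra are generated and the patches are convex mixtures of
    them, so the set lies in a low-dimensional affine span (convexity
    preserves the clipping range).
    """

    n_patches: int = 24
    n_gaussians: int = 4
    baseline: float = 0.4
    baseline_range: tuple = (0.15, 0.65)
    amplitude_range: tuple = (-0.30, 0.30)
    center_range: tuple = (380.0, 780.0)
    width_range: tuple = (40.0, 120.0)
    rank: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gaussians < 0 or self.n_gaussians > 4:
            raise DomainError("n_gaussians must lie in [0, 4]")
        if self.rank is not None and not 2 <= self.rank <= self.n_patches:
            raise DomainError("rank must lie in [2, n_patches]")


def _smooth_spectrum(rng: np.random.Generator, cfg: SyntheticCheckerConfig) -> np.ndarray:
    base = rng.uniform(*cfg.baseline_range)
    values = np.full(N_BANDS, base)
    for _ in range(cfg.n_gaussians):
        amp = rng.uniform(*cfg.amplitude_range)
        center = rng.uniform(*cfg.center_range)
        width = rng.uniform(*cfg.width_range)
        values += amp * np.exp(-0.5 * ((WAVELENGTHS - center) / width) ** 2)
    return np.clip(values, 0.02, 0.98)


def generate_reflectance_set(config: SyntheticCheckerConfig) -> list:
    """Smooth synthetic patch reflectance spectra, reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    if config.n_gaussians == 0:
        return [
            Spectrum(np.full(N_BANDS, config.baseline)) for _ in range(config.n_patches)
        ]
    if config.rank is None:
        return [Spectrum(_smooth_spectrum(rng, config)) for _ in range(config.n_patches)]
    endmembers = np.stack([_smooth_spectrum(rng, config) for _ in range(config.rank)])
    weights = rng.dirichlet(np.full(config.rank, 0.6), size=config.n_patches)
    return [Spectrum(w @ endmembers) for w in weights]


# Planck constants folded into nm-friendly radiance units.
_C2_NM_K = 1.4387768775039337e7  # hc/kB in nm*K


def generate_illuminant(kind: str, T: float = 6504.0, centers=(415.0, 540.0), widths=(10.0, 10.0)) -> Spectrum:
    """An illuminant spectrum: ``flat``, ``blackbody`` (Planck at T), or
    ``dual_narrowband`` (Gaussian lines, emulating an NBI source)."""
    if kind == "flat":
        return Spectrum(np.ones(N_BANDS), "illuminant")
    if kind == "blackbody":
        if T <= 0:
            raise DomainError(f"blackbody temperature must be positive, got {T}")
        lam = WAVELENGTHS
        radiance = lam**-5 / np.expm1(_C2_NM_K / (lam * T))
        return Spectrum(radiance / radiance.max(), "illuminant")
    if kind == "dual_narrowband":
        if len(centers) != len(widths):
            raise DomainError("centers and widths must have equal lengths")
        values = np.zeros(N_BANDS)
        for c, w in zip(centers, widths):
            if w <= 0:
                raise DomainError(f"narrowband width must be positive, got {w}")
            values += np.exp(-0.5 * ((WAVELENGTHS - c) / w) ** 2)
        return Spectrum(values, "illuminant")
    raise DomainError(f"unknown illuminant kind {kind!r}")


def forward_camera(
    spectra,
    illuminant: Spectrum,
    cmfs: CmfSet,
    distortion: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    adaptation: str = "bradford",
) -> np.ndarray:
    """Render reflectance spectra to camera sRGB triples under an illuminant.

    Inverts the calibration chain: tristimulus integration under the
    source, optional linear XYZ distortion (a 3x3 matrix modelling sensor
    crosstalk; linear maps keep the inverse relation polynomial), chromatic
    adaptation from the source white to D65, inverse sRGB primaries, then
    multiplicative Gaussian noise on linear RGB and gamma encoding.
    Output is clipped to [0, 1].
    """
    if isinstance(spectra, Spectrum):
        R = spectra.values[None, :]
    elif isinstance(spectra, np.ndarray):
        R = np.atleast_2d(spectra)
    else:
        R = np.stack([s.values if isinstance(s, Spectrum) else np.asarray(s) for s in spectra])
    xyz = spectra_to_xyz(illuminant, R, cmfs)
    if distortion is not None:
        xyz = xyz @ np.asarray(distortion, dtype=float).T
    white = source_white_point(illuminant, cmfs)
    M = adaptation_matrix(white, D65, method=adaptation)
    xyz_d65 = xyz @ M.T
    lin = xyz_d65 / 100.0 @ np.linalg.inv(SRGB_TO_XYZ).T
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        lin = lin * (1.0 + noise_sigma * rng.standard_normal(lin.shape))
    return encode_srgb(np.clip(lin, 0.0, 1.0))


def mucosa_reflectance() -> Spectrum:
    """Pink mucosa-like background reflectance: high in the red, mild heme dips."""
    lam = WAVELENGTHS
    values = 0.30 + 0.38 / (1.0 + np.exp(-(lam - 590.0) / 35.0))
    values -= 0.06 * np.exp(-0.5 * ((lam - 415.0) / 22.0) ** 2)
    values -= 0.04 * np.exp(-0.5 * ((lam - 540.0) / 25.0) ** 2)
    return Spectrum(np.clip(values, 0.02, 0.98))


def vessel_reflectance() -> Spectrum:
    """Hemoglobin-like vessel reflectance: strong 415 nm dip, secondary 540 nm dip."""
    base = mucosa_reflectance().values * 0.72
    values = (
        base
        - 0.16 * np.exp(-0.5 * ((WAVELENGTHS - 415.0) / 18.0) ** 2)
        - 0.10 * np.exp(-0.5 * ((WAVELENGTHS - 540.0) / 22.0) ** 2)
    )
    return Spectrum(np.clip(values, 0.02, 0.98))


@dataclass
class PhantomScene:
    """A rendered vessel phantom with exact region masks and ground truth."""

    image: np.ndarray  # uint8 HxWx3
    masks: RegionMasks
    background_reflectance: Spectrum
    vessel_reflectance: Spectrum
    seed: int


def _draw_vessels(rng: np.random.Generator, size: int, n_vessels: int) -> np.ndarray:
    """Random-walk curvilinear strokes, width 2-6 px, as a boolean mask."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_vessels):
        pos = rng.uniform(0.1 * size, 0.9 * size, size=2)
        angle = rng.uniform(0, 2 * np.pi)
        radius = rng.integers(1, 4)  # brush radius 1-3 px -> width 2-6 px
        n_steps = int(size * 0.9)
        step = 2.5
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.18)
            pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                break
            r, c = int(pos[0]), int(pos[1])
            r0, r1 = max(r - 3, 0), min(r + 4, size)
            c0, c1 = max(c - 3, 0), min(c + 4, size)
            local = (yy[r0:r1, c0:c1] - pos[0]) ** 2 + (xx[r0:r1, c0:c1] - pos[1]) ** 2
            mask[r0:r1, c0:c1] |= local <= radius**2
    return mask


def generate_phantom(
    seed: int = 0,
    size: int = 380,
    n_vessels: int = 8,
    illuminant: Spectrum | None = None,
    cmfs: CmfSet | None = None,
    noise_sigma: float = 0.01,
) -> PhantomScene:
    """Render a vessel phantom frame with ground-truth masks.

    Vessel strokes carry hemoglobin-like reflectance (415/540 nm dips) on a
    pink mucosa background; a smooth illumination falloff, light blur and
    multiplicative sensor noise make the frame photographically plausible.
    The background mask excludes a 3 px guard band around vessels so blur
    does not contaminate region statistics. Deterministic per seed.
    """
    if size < 64:
        raise DomainError(f"phantom size must be >= 64, got {size}")
    from .spectral import load_default_cmfs  # local import avoids cycle at module load

    if cmfs is None:
        cmfs = load_default_cmfs()
    if illuminant is None:
        illuminant = generate_illuminant("blackbody", T=6504.0)
    rng = np.random.default_rng(seed)

    bg_spec = mucosa_reflectance()
    vs_spec = vessel_reflectance()
    rgb_pair = forward_camera([bg_spec, vs_spec], illuminant, cmfs)
    bg_rgb, vs_rgb = rgb_pair[0], rgb_pair[1]

    vessel_mask = _draw_vessels(rng, size, n_vessels)
    img = np.where(vessel_mask[:, :, None], vs_rgb, bg_rgb)

    # smooth vignette-like illumination field
    cy, cx = rng.uniform(0.3 * size, 0.7 * size, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    dist2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (size**2)
    shading = 1.0 - 0.25 * dist2
    lin = colorcal.linearize_srgb(img) * shading[:, :, None]
    if noise_sigma > 0:
        lin = lin * (1.0 + noise_sigma * rng.standard_normal(lin.shape))
    lin = gaussian_filter(np.clip(lin, 0.0, 1.0), sigma=(0.8, 0.8, 0.0))
    img8 = np.clip(np.rint(encode_srgb(np.clip(lin, 0.0, 1.0)) * 255.0), 0, 255).astype(np.uint8)

    guard = binary_dilation(vessel_mask, iterations=3)
    masks = RegionMasks(vessel=vessel_mask, background=~guard)
    return PhantomScene(
        image=img8,
        masks=masks,
        background_reflectance=bg_spec,
        vessel_reflectance=vs_spec,
        seed=seed,
    )
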