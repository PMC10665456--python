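import numpy as np
import pytest

from endospect import SpectralReconstructor
from endospect.spectral import load_default_cmfs
from endospect.synthetic import (
    SyntheticCheckerConfig,
    forward_camera,
    generate_illuminant,
    generate_phantom,
    generate_reflectance_set,
)

# Mild sensor-crosstalk distortion: linear, hence exactly invertible by the
# polynomial correction stage.
LINEAR_DISTORTION = np.eye(3) + np.array(
    [[0.0, 0.04, -0.02], [0.03, 0.0, 0.01], [-0.01, 0.02, 0.0]]
)


@pytest.fixture(scope="session")
def cmfs():
    return load_default_cmfs()


@pytest.fixture(scope="session")
def illuminant():
    return generate_illuminant("blackbody", T=6504.0)


@pytest.fixture(scope="session")
def checker_rank4(illuminant, cmfs):
    """Noise-free checker whose spectra span a 3-D affine subspace.

    With only three tristimulus coordinates per pixel, exact spectral
    recovery is possible only when the spectral variation itself is at
    most three-dimensional; rank-4 convex mixtures realize that setting.
    """
    cfg = SyntheticCheckerConfig(rank=4, seed=0)
    spectra = generate_reflectance_set(cfg)
    srgb = forward_camera(spectra, illuminant, cmfs, distortion=LINEAR_DISTORTION)
    return srgb, spectra


@pytest.fixture(scope="session")
def fitted_rank4(checker_rank4, illuminant, cmfs):
    srgb, spectra = checker_rank4
    est = SpectralReconstructor(illuminant=illuminant, cmfs=cmfs, n_components=12)
    return est.fit(srgb, spectra)


@pytest.fixture(scope="session")
def checker_free(illuminant, cmfs):
    """Unconstrained smooth checker spanning a wide gamut (realistic case)."""
    cfg = SyntheticCheckerConfig(seed=0)
    spectra = generate_reflectance_set(cfg)
    srgb = forward_camera(spectra, illuminant, cmfs)
    return srgb, spectra


@pytest.fixture(scope="session")
def fitted_free(checker_free, illuminant, cmfs):
    srgb, spectra = checker_free
    est = SpectralReconstructor(illuminant=illuminant, cmfs=cmfs, n_components=12)
    return est.fit(srgb, spectra)


@pytest.fixture(scope="session")
def phantom(illuminant, cmfs):
    return generate_phantom(seed=1, size=128, illuminant=illuminant, cmfs=cmfs)
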