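"""File formats: spectrum/checker CSVs, ENVI cubes, calibration JSON, images, masks.

Conventions: row-major arrays, top-left origin, 0-based indices. ENVI
cubes are written as an ASCII ``.hdr`` plus a band-sequential (BSQ)
little-endian float32 payload; a compressed ``.npz`` container with
identical content is available for convenience.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .colorcal import CameraCalibration
from .errors import FormatError, ShapeError
from .spectral import (
    HyperspectralCube,
    N_BANDS,
    ReflectanceBasis,
    Spectrum,
    SpectralTransform,
    WAVELENGTHS,
)

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_checker_csv",
    "write_checker_csv",
    "write_cube_envi",
    "read_cube_envi",
    "write_cube_npz",
    "read_cube_npz",
    "save_calibration",
    "load_calibration",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


def read_spectrum_csv(path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column (wavelength_nm, value) spectrum CSV on the 401-sample grid."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["wavelength_nm", "value"]:
        raise FormatError(f"{path}:1: expected header 'wavelength_nm,value', got {lines[0]!r}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{i}: non-numeric or malformed row {line!r}") from None
    if len(rows) != N_BANDS:
        raise FormatError(f"{path}: expected {N_BANDS} samples, got {len(rows)}")
    wl = np.array([r[0] for r in rows])
    if not np.array_equal(wl, WAVELENGTHS):
        bad = int(np.argmax(wl != WAVELENGTHS)) + 2
        raise FormatError(f"{path}:{bad}: wavelength grid must be 380..780 nm step 1")
    return Spectrum(np.array([r[1] for r in rows]), kind)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(WAVELENGTHS, spectrum.values):
            fh.write(f"{w:.0f},{float(v):.17g}\n")


def read_checker_csv(path):
    """Read a color-checker calibration CSV.

    One row per patch: patch_id, R, G, B (0-255 scale, floats allowed),
    then 401 reflectance columns labeled by wavelength. Returns
    ``(srgb, spectra)`` with sRGB scaled to [0, 1].
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if len(header) != 4 + N_BANDS or header[:4] != ["patch_id", "R", "G", "B"]:
        raise FormatError(
            f"{path}:1: expected header patch_id,R,G,B followed by {N_BANDS} "
            f"wavelength columns"
        )
    srgb, spectra = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 4 + N_BANDS:
            raise FormatError(f"{path}:{i}: expected {4 + N_BANDS} fields, got {len(parts)}")
        try:
            rgb = [float(p) for p in parts[1:4]]
            refl = [float(p) for p in parts[4:]]
        except ValueError:
            raise FormatError(f"{path}:{i}: non-numeric value") from None
        srgb.append(rgb)
        spectra.append(Spectrum(np.array(refl)))
    return np.asarray(srgb) / 255.0, spectra


def write_checker_csv(srgb, spectra, path) -> None:
    """Write matched (sRGB in [0, 1], reflectance spectrum) calibration pairs."""
    srgb = np.asarray(srgb, dtype=float)
    if srgb.ndim != 2 or srgb.shape[1] != 3 or srgb.shape[0] != len(spectra):
        raise ShapeError("srgb must be (n, 3) matching the spectra list")
    path = Path(path)
    wl_cols = ",".join(f"refl_{w:.0f}" for w in WAVELENGTHS)
    with path.open("w") as fh:
        fh.write(f"patch_id,R,G,B,{wl_cols}\n")
        for i, (rgb, spec) in enumerate(zip(srgb, spectra), start=1):
            vals = spec.values if isinstance(spec, Spectrum) else np.asarray(spec)
            fh.write(
                f"{i},{float(rgb[0]) * 255.0:.17g},{float(rgb[1]) * 255.0:.17g},"
                f"{float(rgb[2]) * 255.0:.17g},"
                + ",".join(f"{float(v):.17g}" for v in vals)
                + "\n"
            )


def _envi_paths(path):
    path = Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".img")
    return path.with_suffix(".hdr"), path.with_suffix(".img")


def write_cube_envi(cube: HyperspectralCube, path) -> None:
    """Write an ENVI cube: ASCII header + BSQ float32 little-endian payload."""
    hdr_path, img_path = _envi_paths(path)
    H, W, B = cube.data.shape
    wl = ", ".join(f"{w:.1f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {endospect reflectance cube}\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    bsq = np.ascontiguousarray(np.moveaxis(cube.data.astype("<f4"), 2, 0))
    bsq.tofile(img_path)


def _parse_envi_header(text: str, path) -> dict:
    if not text.startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    fields = {}
    key, buf, in_braces = None, "", False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf, in_braces = val, True
        else:
            fields[key] = val
    return fields


def read_cube_envi(path) -> HyperspectralCube:
    """Read an ENVI cube written by :func:`write_cube_envi` (validates payload size)."""
    hdr_path, img_path = _envi_paths(path)
    fields = _parse_envi_header(hdr_path.read_text(), hdr_path)
    try:
        W = int(fields["samples"])
        H = int(fields["lines"])
        B = int(fields["bands"])
    except (KeyError, ValueError):
        raise FormatError(f"{hdr_path}: missing or malformed samples/lines/bands") from None
    if fields.get("data type") != "4" or fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{hdr_path}: only BSQ float32 (data type 4) cubes are supported")
    raw = np.fromfile(img_path, dtype="<f4")
    if raw.size != H * W * B:
        raise FormatError(
            f"{img_path}: payload has {raw.size} values, header implies {H * W * B} "
            "(truncated or corrupt)"
        )
    data = np.moveaxis(raw.reshape(B, H, W), 0, 2)
    wl_field = fields.get("wavelength", "")
    wl_vals = [v for v in wl_field.strip("{} ").replace("\n", " ").split(",") if v.strip()]
    wavelengths = np.array([float(v) for v in wl_vals]) if len(wl_vals) == B else WAVELENGTHS
    return HyperspectralCube(data=data, wavelengths=wavelengths)


def write_cube_npz(cube: HyperspectralCube, path) -> None:
    """Single-file compressed container with the same content as the ENVI pair."""
    np.savez_compressed(path, data=cube.data.astype(np.float32), wavelengths=cube.wavelengths)


def read_cube_npz(path) -> HyperspectralCube:
    with np.load(path) as z:
        return HyperspectralCube(data=z["data"], wavelengths=z["wavelengths"])


def save_calibration(path, calib: CameraCalibration, basis: ReflectanceBasis,
                     transform: SpectralTransform, extra: dict | None = None) -> None:
    """Serialize the fitted calibration artifacts as JSON (matrices as nested lists)."""
    payload = {
        "format": "endospect-calibration-v1",
        "camera": {
            "T": calib.T.tolist(),
            "M_A": calib.M_A.tolist(),
            "regressor_spec": [list(t) for t in calib.regressor_spec],
            "C": calib.C.tolist() if calib.C is not None else None,
        },
        "basis": {
            "mean": basis.mean.tolist(),
            "components": basis.components.tolist(),
            "scores": basis.scores.tolist(),
            "explained_variance": basis.explained_variance.tolist(),
        },
        "transform": {
            "M": transform.M.tolist(),
            "regressor_spec": [list(t) for t in transform.regressor_spec],
        },
    }
    if extra:
        payload["extra"] = extra
    Path(path).write_text(json.dumps(payload))


def load_calibration(path):
    """Load calibration artifacts; returns (CameraCalibration, ReflectanceBasis,
    SpectralTransform, extra-dict)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    if payload.get("format") != "endospect-calibration-v1":
        raise FormatError(f"{path}: not an endospect calibration file")
    cam, bas, tr = payload["camera"], payload["basis"], payload["transform"]
    calib = CameraCalibration(
        T=np.array(cam["T"]),
        M_A=np.array(cam["M_A"]),
        regressor_spec=[tuple(t) for t in cam["regressor_spec"]],
        C=np.array(cam["C"]) if cam["C"] is not None else None,
    )
    basis = ReflectanceBasis(
        mean=np.array(bas["mean"]),
        components=np.array(bas["components"]),
        scores=np.array(bas["scores"]),
        explained_variance=np.array(bas["explained_variance"]),
    )
    transform = SpectralTransform(
        M=np.array(tr["M"]),
        regressor_spec=[tuple(t) for t in tr["regressor_spec"]],
    )
    return calib, basis, transform, payload.get("extra", {})


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF image as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return arr


def write_image(image: np.ndarray, path) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG; nonzero pixels are region members."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)
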