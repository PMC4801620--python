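"""Hypercube I/O and image-domain operations.

A near-infrared hyperspectral camera produces a cube of raw counts
(rows x cols x bands) together with flat-field references: a white tile
(~100 % reflectance) and a closed-shutter dark frame (~0 %).  This module
reads and writes such cubes in the plain ENVI format (binary raster +
ASCII header), converts raw counts to relative reflectance,

    R = (I_raw - I_dark) / (I_white - I_dark),

crops the cube to a spectral working range, segments the Petri-dish
region of interest, and extracts per-pixel spectra as a matrix.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, erosion

__all__ = [
    "Hypercube",
    "ROIMask",
    "SpectraMatrix",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "crop_bands",
    "segment_dish",
    "extract_roi_spectra",
]


class EnviFormatError(ValueError):
    """Raised when an ENVI header/raster pair is inconsistent or unsupported."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Hypercube:
    """A hyperspectral cube: ``data[row, col, band]`` plus a wavelength axis.

    ``data`` holds raw counts or reflectance; invalid pixels carry NaN and a
    boolean validity plane may sit in ``meta['valid']``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ROIMask:
    """Boolean region-of-interest grid (True = analysed pixel)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectraMatrix:
    """n_samples x n_bands spectra with a shared wavelength axis and ids."""

    data: np.ndarray
    wavelengths: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("spectra matrix must be 2-D")
        if self.data.shape[1] != len(self.wavelengths):
            raise ValueError("band count does not match wavelength axis")
        if len(self.ids) != self.data.shape[0]:
            raise ValueError("id list length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path: str | os.PathLike) -> None:
        cols = [f"{wl:.4f}" for wl in self.wavelengths]
        df = pd.DataFrame(self.data, columns=cols)
        df.insert(0, "id", [str(i) for i in self.ids])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SpectraMatrix":
        df = pd.read_csv(path)
        ids = df["id"].astype(str).tolist()
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(df.iloc[:, 1:].to_numpy(float), wl, ids)


# ---------------------------------------------------------------------------
# ENVI raster + header codec
# ---------------------------------------------------------------------------

# ENVI 'data type' codes for the dtypes this codec supports
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}
_INTERLEAVES = ("bsq", "bil", "bip")


def _header_path(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base + ".hdr" if ext != ".hdr" else path


def _raster_path(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base + ".img" if ext == ".hdr" else path


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value:
                value += " " + next(lines).strip()
            value = value.strip("{} ").strip()
        fields[key] = value
    return fields


def read_envi(path: str | os.PathLike) -> Hypercube:
    """Read an ENVI raster/header pair into a :class:`Hypercube`.

    ``path`` may point at either the raster (``.img``) or header (``.hdr``).
    """
    path = str(path)
    hdr_path, img_path = _header_path(path), _raster_path(path)
    if not os.path.exists(hdr_path):
        raise EnviFormatError(f"missing ENVI header: {hdr_path}")
    if not os.path.exists(img_path):
        raise EnviFormatError(f"missing ENVI raster: {img_path}")
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())

    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise EnviFormatError(f"ENVI header missing field '{req}'")
    samples, lines_, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI field 'data type' = {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported ENVI field 'interleave' = {interleave!r}")
    if int(fields.get("byte order", 0)) != 0:
        raise EnviFormatError("unsupported ENVI field 'byte order' (expect 0)")

    dtype = np.dtype(_ENVI_DTYPES[code])
    expected = samples * lines_ * bands * dtype.itemsize
    actual = os.path.getsize(img_path)
    if expected != actual:
        raise EnviFormatError(
            f"raster size {actual} bytes does not match header fields "
            f"samples/lines/bands/data type (expected {expected} bytes)"
        )
    flat = np.fromfile(img_path, dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, lines_, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines_, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines_, samples, bands)

    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].split(",")])
        if len(wl) != bands:
            raise EnviFormatError("ENVI field 'wavelength' length does not match bands")
    else:
        wl = np.arange(bands, dtype=float)
    meta = {"interleave": interleave, "source": img_path}
    return Hypercube(np.ascontiguousarray(data), wl, meta)


def write_envi(
    cube: Hypercube,
    path: str | os.PathLike,
    interleave: str = "bsq",
    dtype: np.dtype | type | None = None,
) -> str:
    """Write ``cube`` as an ENVI raster + header; returns the raster path."""
    path = str(path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    dt = np.dtype(dtype if dtype is not None else cube.data.dtype)
    if dt not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported dtype {dt}")
    data = np.asarray(cube.data, dtype=dt)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    img_path, hdr_path = _raster_path(path), _header_path(path)
    np.ascontiguousarray(out).tofile(img_path)
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return img_path


# ---------------------------------------------------------------------------
# reflectance calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Convert raw counts to relative reflectance with white/dark references.

    Elements where ``white - dark <= 0`` are flagged invalid: they become NaN
    and the per-pixel validity plane is stored in ``meta['valid']`` (True where
    every band of the pixel is valid).
    """
    for other, name in ((white, "white"), (dark, "dark")):
        if other.data.shape != raw.data.shape:
            raise ValueError(f"{name} reference shape {other.data.shape} "
                             f"does not match raw {raw.data.shape}")
        if not np.allclose(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference wavelength axis differs from raw")
    denom = white.data.astype(float) - dark.data.astype(float)
    invalid = denom <= 0
    if invalid.all():
        raise ValueError("reflectance calibration invalid everywhere (white <= dark)")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(float) - dark.data.astype(float)) / denom
    refl[invalid] = np.nan
    valid_plane = ~invalid.any(axis=2)
    meta = dict(raw.meta)
    meta.update(calibrated=True, valid=valid_plane)
    return Hypercube(refl, raw.wavelengths.copy(), meta)


def crop_bands(cube: Hypercube, lo_nm: float, hi_nm: float, tol: float = 1e-6) -> Hypercube:
    """Keep bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive ends).

    A small tolerance absorbs floating-point jitter in axes whose endpoints
    are meant to coincide with the crop bounds.
    """
    if lo_nm > hi_nm:
        raise ValueError("crop range is empty (lo_nm > hi_nm)")
    sel = (cube.wavelengths >= lo_nm - tol) & (cube.wavelengths <= hi_nm + tol)
    if not sel.any():
        raise ValueError(
            f"crop range [{lo_nm}, {hi_nm}] nm does not intersect the axis "
            f"[{cube.wavelengths[0]:.2f}, {cube.wavelengths[-1]:.2f}] nm"
        )
    meta = dict(cube.meta)
    meta["crop_nm"] = (lo_nm, hi_nm)
    return Hypercube(cube.data[:, :, sel], cube.wavelengths[sel], meta)


# ---------------------------------------------------------------------------
# ROI segmentation and spectra extraction
# ---------------------------------------------------------------------------

def segment_dish(
    cube: Hypercube,
    reference_band: int | None = None,
    erode_px: int = 0,
) -> ROIMask:
    """Segment the Petri-dish interior at a single reference band.

    Otsu threshold -> largest connected foreground component -> morphological
    erosion by ``erode_px`` to shave off the dish rim, whose spectrum differs
    from the liquid.
    """
    if reference_band is None:
        reference_band = cube.n_bands // 2
    if not 0 <= reference_band < cube.n_bands:
        raise ValueError(f"reference_band {reference_band} out of range")
    if erode_px < 0:
        raise ValueError("erode_px must be >= 0")
    img = np.nan_to_num(cube.data[:, :, reference_band], nan=0.0)
    if np.ptp(img) == 0:
        raise ValueError("no foreground component found (uniform image)")
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        raise ValueError("no foreground component found")
    labels = label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    if erode_px > 0:
        mask = erosion(mask, disk(erode_px))
    if not mask.any():
        raise ValueError("ROI empty after erosion; reduce erode_px")
    return ROIMask(mask)


def extract_roi_spectra(cube: Hypercube, roi: ROIMask) -> SpectraMatrix:
    """Extract one spectrum per ROI pixel, in row-major pixel order."""
    if roi.mask.shape != cube.data.shape[:2]:
        raise ValueError("ROI grid shape does not match cube spatial shape")
    if roi.n_pixels < 1:
        raise ValueError("empty ROI")
    coords = np.argwhere(roi.mask)  # row-major order
    spectra = cube.data[roi.mask]   # same order as argwhere
    ids = [f"px_{r}_{c}" for r, c in coords]
    return SpectraMatrix(spectra, cube.wavelengths.copy(), ids)
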