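"""Hyperspectral cubes: containers, ENVI/HDF5 I/O, reflectance calibration, ROIs.

A cube is a rows x cols x bands array with a strictly increasing wavelength
vector in nanometres.  Raw digital numbers are converted to reflectance with
the whiteboard correction

    R = (RO - RD) / (RW - RD)

where RO is the raw cube and RW / RD are white and dark reference cubes
sharing its geometry.  Spectra are extracted as per-band means over an
elliptical region of interest placed on the fruit surface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import CalibrationError, ContractError, FormatError

__all__ = [
    "Hypercube",
    "CalibrationPair",
    "ROISpec",
    "read_envi_cube",
    "write_envi_cube",
    "read_hdf5_cube",
    "write_hdf5_cube",
    "reflectance_correct",
    "elliptical_roi_mask",
    "mean_roi_spectrum",
]

# ENVI "data type" codes for the subset of dtypes this reader supports.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """rows x cols x bands array plus band-centre wavelengths (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ContractError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ContractError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ContractError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("cube data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationPair:
    """White (RW) and dark (RD) reference cubes for whiteboard correction."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        if self.white.shape != self.dark.shape:
            raise ContractError("white and dark references must share shape")
        if not np.allclose(self.white.wavelengths, self.dark.wavelengths):
            raise ContractError("white and dark references must share wavelengths")


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned elliptical region of interest, 0-based pixel coordinates.

    The study places the ellipse on the fruit's equatorial zone with the major
    axis along the stem-calyx axis; axes of 90 x 60 px correspond to semi-axes
    45 / 30.
    """

    center_row: float
    center_col: float
    semi_major: float
    semi_minor: float
    orientation: str = "row-aligned"  # major axis along rows or cols

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ContractError("require semi_major >= semi_minor > 0")
        if self.orientation not in ("row-aligned", "col-aligned"):
            raise ContractError("orientation must be 'row-aligned' or 'col-aligned'")


# ---------------------------------------------------------------------------
# ENVI-style I/O (text header + flat binary data file)
# ---------------------------------------------------------------------------


def _parse_envi_header(text: str) -> dict[str, str]:
    # collapse { ... } blocks (possibly multi-line) before splitting key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(header_path: str | Path) -> Hypercube:
    """Read an ENVI header/data pair into a :class:`Hypercube`.

    The data file is located by dropping the header's ``.hdr`` suffix, or via
    an explicit ``data file`` key.  Supported interleaves: bsq, bil, bip.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header not found: {header_path}")
    fields = _parse_envi_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"header missing required key: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    interleave = fields.get("interleave", "bsq").lower()

    wl_field = fields.get("wavelength", "")
    wl_values = re.findall(r"[-+0-9.eE]+", wl_field)
    if len(wl_values) != bands:
        raise FormatError(
            f"header declares {bands} bands but {len(wl_values)} wavelengths"
        )
    wavelengths = np.array([float(v) for v in wl_values])

    data_path = fields.get("data file")
    if data_path is not None:
        data_path = header_path.parent / data_path
    else:
        data_path = header_path.with_suffix("")
        if not data_path.exists():
            data_path = header_path.with_suffix(".dat")
    if not Path(data_path).exists():
        raise FileNotFoundError(f"data file not found for header {header_path}")

    raw = np.fromfile(data_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"data file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")

    meta = {k: v for k, v in fields.items()
            if k not in {"lines", "samples", "bands", "data type", "wavelength",
                         "interleave", "data file", "byte order"}}
    return Hypercube(data.astype(np.float64), wavelengths, meta)


def write_envi_cube(cube: Hypercube, header_path: str | Path,
                    dtype: str = "float32", interleave: str = "bsq") -> Path:
    """Write ``cube`` as an ENVI header (+ ``.dat``) pair; returns header path."""
    header_path = Path(header_path)
    dt = np.dtype(dtype)
    if dt not in _ENVI_CODES:
        raise FormatError(f"unsupported output dtype {dtype}")
    data_path = header_path.with_suffix(".dat")
    rows, cols, bands = cube.shape
    if interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = cube.data.transpose(0, 2, 1)
    elif interleave == "bip":
        out = cube.data
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    np.ascontiguousarray(out, dtype=dt).tofile(data_path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data file = {data_path.name}\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    for key, value in cube.metadata.items():
        header += f"{key} = {value}\n"
    header_path.write_text(header)
    return header_path


def write_hdf5_cube(cube: Hypercube, path: str | Path) -> Path:
    """Portable HDF5 container with /data, /wavelengths and /metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        grp = f.create_group("metadata")
        for key, value in cube.metadata.items():
            grp.attrs[key] = str(value)
    return path


def read_hdf5_cube(path: str | Path) -> Hypercube:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        wavelengths = f["wavelengths"][...]
        meta = {k: str(v) for k, v in f["metadata"].attrs.items()}
    return Hypercube(data, wavelengths, meta)


# ---------------------------------------------------------------------------
# Calibration and ROI extraction
# ---------------------------------------------------------------------------


def reflectance_correct(raw: Hypercube, cal: CalibrationPair,
                        fill_value: float = 0.0,
                        clip_negative: bool = True) -> Hypercube:
    """Whiteboard correction R = (RO - RD) / (RW - RD).

    Elements where the white and dark references coincide carry no calibration
    information; they are set to ``fill_value`` and their count is recorded in
    the output metadata under ``invalid_pixels`` so whole-cube calibration
    survives dead detector elements.  Negative reflectance is clipped to 0 by
    default; values above 1 (specular highlights) are retained.
    """
    if raw.shape != cal.white.shape:
        raise ContractError("raw cube and calibration frames must share shape")
    if not np.allclose(raw.wavelengths, cal.white.wavelengths):
        raise ContractError("raw cube and calibration frames must share wavelengths")
    denom = cal.white.data - cal.dark.data
    invalid = denom == 0
    if invalid.all():
        raise CalibrationError("white and dark references are identical everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - cal.dark.data) / denom
    refl = np.where(invalid, fill_value, refl)
    if clip_negative:
        refl = np.maximum(refl, 0.0)
    meta = dict(raw.metadata)
    meta["invalid_pixels"] = str(int(invalid.sum()))
    meta["calibrated"] = "whiteboard"
    return Hypercube(refl, raw.wavelengths.copy(), meta)


def elliptical_roi_mask(shape: tuple[int, int], roi: ROISpec) -> np.ndarray:
    """Boolean mask of the pixels inside an axis-aligned ellipse.

    A pixel (r, c) is inside iff ((r-cr)/a)^2 + ((c-cc)/b)^2 <= 1, with the
    semi-major axis ``a`` along rows for 'row-aligned' orientation (the scan
    direction) and along columns otherwise.
    """
    rows, cols = shape
    if roi.orientation == "row-aligned":
        a, b = roi.semi_major, roi.semi_minor
    else:
        a, b = roi.semi_minor, roi.semi_major
    if (roi.center_row - a < -0.5 or roi.center_row + a > rows - 0.5
            or roi.center_col - b < -0.5 or roi.center_col + b > cols - 0.5):
        raise ContractError("ellipse exceeds image bounds")
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return ((r - roi.center_row) / a) ** 2 + ((c - roi.center_col) / b) ** 2 <= 1.0


def mean_roi_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the spectra under ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ContractError(
            f"mask shape {mask.shape} does not match cube spatial shape {cube.shape[:2]}"
        )
    if not mask.any():
        raise ContractError("ROI mask selects no pixels")
    return cube.data[mask].mean(axis=0)
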