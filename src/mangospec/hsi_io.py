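"""ENVI-style hyperspectral cube I/O, reflectance calibration and ROI extraction.

A line-scan NIR camera produces a cube of digital numbers (lines x samples x
bands).  Calibration against a white reference (PTFE board) and a dark frame
(capped lens) converts counts to percent reflectance,

    R = (I0 - B) / (W - B) * 100,

which is then expressed as absorbance A = log10(100 / R) (the log 1/R mode).
The mean spectrum over a region-of-interest mask — here the bruised area of a
fruit — is the per-sample observation fed to the chemometric models.

Coordinate convention: pixels are addressed (line, sample), 0-based; bands are
indexed by position on the wavelength grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "ReferenceFrames",
    "RoiMask",
    "Spectrum",
    "default_grid",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "reflectance_to_absorbance",
    "absorbance_to_reflectance",
    "extract_roi_mean",
    "EnviFormatError",
    "EnviCorruptionError",
]

#: Division guard for the calibration denominator W - B, in raw-count units.
CALIBRATION_EPS = 1e-6

# ENVI numeric data-type codes supported by this dialect.
_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}


class EnviFormatError(ValueError):
    """Header is missing required metadata or uses an unsupported dialect."""


class EnviCorruptionError(IOError):
    """Binary payload size disagrees with the header dimensions."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing spectral axis in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least 2 bands")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if vals[0] < 300 or vals[-1] > 2600:
            raise ValueError("wavelengths outside the plausible 300-2600 nm range")

    @property
    def count(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


def default_grid() -> WavelengthGrid:
    """The instrument grid: 256 evenly spaced bands spanning 900-1700 nm."""
    return WavelengthGrid(np.linspace(900.0, 1700.0, 256))


@dataclass
class Hypercube:
    """3-D intensity array (lines x samples x bands) with its spectral axis.

    ``kind`` is one of ``"raw"`` (digital numbers), ``"reflectance_percent"``
    or ``"absorbance"``.  Invalid pixels (calibration denominator below the
    guard, or non-positive reflectance) are carried as NaN.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"
    cube_id: str = "cube"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube must be lines x samples x bands")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"band axis {self.data.shape[2]} != grid count {self.grid.count}"
            )
        if self.kind not in ("raw", "reflectance_percent", "absorbance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """White (W) and dark (B) calibration frames.

    Either full cubes matching the raw cube, or per-line 2-D frames of shape
    (samples, bands) that broadcast across lines — the usual line-scan
    practice where one reference scan serves the whole acquisition.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim not in (2, 3):
            raise ValueError("reference frames must be 2-D or 3-D")


@dataclass
class RoiMask:
    """Boolean pixel mask (lines x samples) naming a region of interest."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (lines x samples)")
        if not self.mask.any():
            raise ValueError("ROI mask has no true pixel")

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "roi") -> "RoiMask":
        arr = np.loadtxt(path, delimiter=",", dtype=int)
        return cls(np.atleast_2d(arr) != 0, label=label)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.mask.astype(int), fmt="%d", delimiter=",")


@dataclass
class Spectrum:
    """A single per-band observation on a shared wavelength grid."""

    sample_id: str
    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "absorbance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.count:
            raise ValueError("spectrum length must match grid count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


# ---------------------------------------------------------------------------
# ENVI header + binary container

def _interleave_axes(interleave: str) -> tuple[int, int, int]:
    # Axis order of the on-disk array, expressed as positions of
    # (line, sample, band) in the stored layout.
    return {
        "bip": (0, 1, 2),  # line, sample, band
        "bil": (0, 2, 1),  # line, band, sample
        "bsq": (2, 0, 1),  # band, line, sample
    }[interleave]


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic word")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ").strip()
        fields[key.strip().lower()] = value
    return fields


def _data_path_for(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".img"), stem.with_suffix(".dat"), stem):
        if cand.exists() and cand != header_path:
            return cand
    return stem.with_suffix(".img")


def read_envi_cube(header_path: str | Path) -> Hypercube:
    """Read an ENVI header + flat binary cube into band-interleaved memory.

    Supports BIL/BIP/BSQ interleaves, little-endian uint16 and float32
    payloads, and requires a ``wavelength`` field in the header.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength metadata")
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise EnviFormatError("only little-endian (byte order 0) is supported")

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise EnviFormatError("wavelength list length differs from band count")

    dtype = _ENVI_DTYPES[dtype_code]
    offset = int(fields.get("header offset", "0"))
    data_path = _data_path_for(header_path)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise EnviCorruptionError(
            f"{data_path} holds {raw.size} values, header implies {expected}"
        )

    axes = _interleave_axes(interleave)
    shape_on_disk = tuple((lines, samples, bands)[ax] for ax in axes)
    cube = raw.reshape(shape_on_disk).transpose(np.argsort(axes))
    return Hypercube(
        np.ascontiguousarray(cube),
        WavelengthGrid(wavelengths),
        kind=fields.get("cube kind", "raw"),
        cube_id=header_path.stem,
    )


def write_envi_cube(
    cube: Hypercube, header_path: str | Path, interleave: str = "bil"
) -> Path:
    """Write the cube as ENVI header + flat binary; returns the data path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    header_path = Path(header_path)
    data_path = header_path.with_suffix("").with_suffix(".img")

    axes = _interleave_axes(interleave)
    on_disk = data.transpose(axes)
    on_disk.astype(on_disk.dtype.newbyteorder("<")).tofile(data_path)

    wl = ", ".join(f"{v:.17g}" for v in cube.grid.values)
    lines, samples, bands = data.shape
    header_path.write_text(
        "ENVI\n"
        "description = { mangospec hyperspectral cube }\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return data_path


# ---------------------------------------------------------------------------
# Calibration and spectra

def calibrate_reflectance(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """Dark/white calibration to percent reflectance.

    R = (I0 - B) / (W - B) * 100 per pixel and band.  Pixels where the
    denominator W - B falls below the guard epsilon are set to NaN and
    excluded from downstream ROI means.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw cube")
    white, dark = refs.white, refs.dark
    if white.ndim == 2:
        if white.shape != raw.shape[1:]:
            raise ValueError(
                f"per-line reference shape {white.shape} does not match "
                f"cube (samples, bands) {raw.shape[1:]}"
            )
        white = white[np.newaxis, :, :]
        dark = dark[np.newaxis, :, :]
    elif white.shape != raw.shape:
        raise ValueError("full-cube reference shape does not match the cube")

    denom = white - dark
    valid = denom > CALIBRATION_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(float) - dark) / denom * 100.0
    refl = np.where(valid, refl, np.nan)
    return Hypercube(refl, raw.grid, kind="reflectance_percent", cube_id=raw.cube_id)


def reflectance_to_absorbance(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Percent reflectance -> absorbance A = log10(100 / R).

    Non-positive reflectances cannot be log-transformed; they are masked to
    NaN and counted.  Returns (absorbance, n_masked).
    """
    vals = np.asarray(values, dtype=float)
    bad = ~(vals > 0) & np.isfinite(vals)
    n_masked = int(bad.sum())
    if n_masked:
        warnings.warn(f"{n_masked} non-positive reflectance values masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        absorb = np.log10(100.0 / vals)
    absorb = np.where(bad, np.nan, absorb)
    return absorb, n_masked


def absorbance_to_reflectance(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reflectance_to_absorbance`: R = 100 * 10**(-A)."""
    return 100.0 * np.power(10.0, -np.asarray(values, dtype=float))


def cube_to_absorbance(cube: Hypercube) -> Hypercube:
    if cube.kind != "reflectance_percent":
        raise ValueError("expected a percent-reflectance cube")
    absorb, _ = reflectance_to_absorbance(cube.data)
    return Hypercube(absorb, cube.grid, kind="absorbance", cube_id=cube.cube_id)


def extract_roi_mean(cube: Hypercube, mask: RoiMask) -> Spectrum:
    """Per-band arithmetic mean spectrum over the masked pixels.

    NaN pixels (masked during calibration) are excluded band-wise; a band
    with no valid pixel inside the ROI is an error.
    """
    if cube.kind == "raw":
        raise ValueError("calibrate the cube before extracting ROI spectra")
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube (lines, samples)")
    pixels = cube.data[mask.mask]  # (n_pixels, bands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(pixels, axis=0)
    if not np.all(np.isfinite(mean)):
        raise ValueError("ROI has bands with no valid pixel")
    return Spectrum(
        sample_id=f"{cube.cube_id}:{mask.label}",
        grid=cube.grid,
        values=mean,
        kind=cube.kind,
    )
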