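"""Canonical spectral types, wavelength-grid arithmetic, resampling, and I/O.

All spectra in this package live on a :class:`WavelengthGrid`, by default the
visible range 380–780 nm sampled every 1 nm (401 bands).  Values are stored as
unitless reflectance factors; regression-based reconstruction can overshoot
the physical [0, 1] range, so out-of-range values are allowed in storage and
flagged by :func:`validate_reflectance` — clipping is always an explicit call,
never silent.

Spectral image cubes are exchanged in the ENVI format (text ``.hdr`` plus
band-sequential little-endian float32 ``.raw``), the de facto standard for
hyperspectral imagery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectralImageCube",
    "RGBImage",
    "SpectralIOError",
    "make_default_grid",
    "resample_spectrum",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_cube",
    "write_cube",
    "read_rgb_image",
    "write_rgb_image",
    "validate_reflectance",
    "clip_reflectance",
]

DEFAULT_START = 380.0
DEFAULT_STOP = 780.0
DEFAULT_STEP = 1.0


class SpectralIOError(ValueError):
    """Malformed spectral file (CSV or ENVI) or inconsistent metadata."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis ``start, start+step, ..., stop`` in nm."""

    start: float = DEFAULT_START
    stop: float = DEFAULT_STOP
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError("grid must be strictly increasing")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide the range exactly")

    @property
    def count(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)

    def index_of(self, wavelength: float) -> int:
        """Index of the grid sample nearest to ``wavelength`` (must be in range)."""
        if not (self.start <= wavelength <= self.stop):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid [{self.start}, {self.stop}]"
            )
        return int(round((wavelength - self.start) / self.step))


def make_default_grid() -> WavelengthGrid:
    """The 380–780 nm, 1 nm, 401-sample visible-light grid."""
    return WavelengthGrid(DEFAULT_START, DEFAULT_STOP, DEFAULT_STEP)


@dataclass
class Spectrum:
    """A single reflectance spectrum on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.count,):
            raise ValueError(
                f"expected {self.grid.count} values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


@dataclass
class SpectralImageCube:
    """H×W×B reflectance cube; the band axis follows ``grid``."""

    grid: WavelengthGrid
    values: np.ndarray  # (H, W, B)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != self.grid.count:
            raise ValueError(
                f"cube band axis must have {self.grid.count} samples, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class RGBImage:
    """H×W×3 image in R,G,B order, values in [0,1].

    ``encoding`` records whether the display transfer function (gamma) has
    been applied: ``"encoded"`` for display-referred values, ``"linear"`` for
    scene-linear values.
    """

    values: np.ndarray  # (H, W, 3)
    encoding: str = "encoded"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got {self.values.shape}")
        if self.encoding not in ("encoded", "linear"):
            raise ValueError(f"unknown encoding {self.encoding!r}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# resampling

def resample_spectrum(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate ``s`` onto ``target``.

    No extrapolation: raises ``ValueError`` if ``target`` extends beyond the
    support of ``s``.  Values at wavelengths shared by both grids are
    unchanged; resampling onto the spectrum's own grid is the identity.
    """
    if target.start < s.grid.start - 1e-9 or target.stop > s.grid.stop + 1e-9:
        raise ValueError(
            f"target grid [{target.start}, {target.stop}] not covered by "
            f"spectrum support [{s.grid.start}, {s.grid.stop}]"
        )
    if target == s.grid:
        return Spectrum(target, s.values.copy())
    values = np.interp(target.wavelengths, s.grid.wavelengths, s.values)
    return Spectrum(target, values)


# ---------------------------------------------------------------------------
# reflectance validation

def validate_reflectance(values: np.ndarray, lo: float = 0.0, hi: float = 1.0):
    """Return (ok, n_below, n_above) for reflectance range checking."""
    arr = np.asarray(values)
    n_below = int(np.sum(arr < lo))
    n_above = int(np.sum(arr > hi))
    return n_below == 0 and n_above == 0, n_below, n_above


def clip_reflectance(values: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Explicit clip of reflectance values to [lo, hi]."""
    return np.clip(np.asarray(values, dtype=float), lo, hi)


# ---------------------------------------------------------------------------
# CSV spectra I/O
#
# Layout: first column "wavelength_nm", one column per spectrum, UTF-8,
# '.' decimal separator.

def write_spectra_csv(path, spectra: list[tuple[str, Spectrum]], decimals: int = 8) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0][1].grid
    for label, s in spectra:
        if s.grid != grid:
            raise ValueError(f"spectrum {label!r} is on a different grid")
    data = {"wavelength_nm": grid.wavelengths}
    for label, s in spectra:
        data[str(label)] = np.round(s.values, decimals)
    pd.DataFrame(data).to_csv(path, index=False, float_format=f"%.{decimals}g")


def read_spectra_csv(path) -> list[tuple[str, Spectrum]]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise SpectralIOError(f"cannot parse CSV {path}: {exc}") from exc
    if "wavelength_nm" not in df.columns:
        raise SpectralIOError(f"{path}: missing 'wavelength_nm' column")
    if df.shape[1] < 2:
        raise SpectralIOError(f"{path}: no spectrum columns")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if len(wl) < 2 or np.any(np.diff(wl) <= 0):
        raise SpectralIOError(f"{path}: wavelengths must be strictly increasing")
    step = wl[1] - wl[0]
    if not np.allclose(np.diff(wl), step):
        raise SpectralIOError(f"{path}: wavelengths must be uniformly spaced")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    out = []
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SpectralIOError(f"{path}: non-finite values in column {col!r}")
        out.append((col, Spectrum(grid, vals)))
    return out


# ---------------------------------------------------------------------------
# ENVI cube I/O (text .hdr + band-sequential float32 little-endian .raw)

_ENVI_DTYPE = {4: "<f4"}  # ENVI data type 4 = 32-bit float


def _raw_path(hdr_path: Path) -> Path:
    for ext in (".raw", ".img", ".dat"):
        cand = hdr_path.with_suffix(ext)
        if cand.exists():
            return cand
    return hdr_path.with_suffix(".raw")


def write_cube(cube: SpectralImageCube, hdr_path) -> None:
    """Write an ENVI header/raw pair; ``hdr_path`` should end in ``.hdr``."""
    hdr_path = Path(hdr_path)
    raw_path = hdr_path.with_suffix(".raw")
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {endospec reflectance cube}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.grid.count}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr, encoding="utf-8")
    # BSQ: band-sequential, band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    bsq.tofile(raw_path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise SpectralIOError("not an ENVI header (missing ENVI magic)")
    # join brace-delimited multi-line values, then split "key = value" lines
    fields: dict[str, str] = {}
    for m in re.finditer(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)$",
                         text, flags=re.MULTILINE | re.DOTALL):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields

def read_cube(hdr_path) -> SpectralImageCube:
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text(encoding="utf-8"))
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise SpectralIOError(f"{hdr_path}: incomplete ENVI header") from exc
    if dtype_code not in _ENVI_DTYPE:
        raise SpectralIOError(f"{hdr_path}: unsupported ENVI data type {dtype_code}")
    if interleave != "bsq":
        raise SpectralIOError(f"{hdr_path}: only bsq interleave supported")
    wl_field = fields.get("wavelength")
    if not wl_field:
        raise SpectralIOError(f"{hdr_path}: header has no wavelength list")
    wl = np.array([float(x) for x in wl_field.strip("{} \n").split(",")])
    if len(wl) != bands:
        raise SpectralIOError(f"{hdr_path}: wavelength list length != bands")
    step = wl[1] - wl[0]
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    raw_path = _raw_path(hdr_path)
    data = np.fromfile(raw_path, dtype=_ENVI_DTYPE[dtype_code])
    expected = samples * lines * bands
    if data.size != expected:
        raise SpectralIOError(
            f"{raw_path}: raw file has {data.size} samples, header implies {expected}"
        )
    cube = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    return SpectralImageCube(grid, cube)


# ---------------------------------------------------------------------------
# PNG / TIFF images

def read_rgb_image(path, encoding: str = "encoded") -> RGBImage:
    """Read a PNG/TIFF image; 8- and 16-bit integers are normalized to [0,1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    return RGBImage(arr, encoding=encoding)


def write_rgb_image(img: RGBImage, path, bitdepth: int = 8) -> None:
    arr = np.clip(img.values, 0.0, 1.0)
    if bitdepth == 8:
        out = np.round(arr * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        out = np.round(arr * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(path, out)
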