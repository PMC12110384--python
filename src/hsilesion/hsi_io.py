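"""Hyperspectral cube container, ENVI I/O, reflectance normalization and QA.

A hyperspectral acquisition is a 3D cube (rows x cols x bands) with a
wavelength axis.  Raw camera counts are converted to reflectance against a
white-standard frame and a dark-current frame,

    R = (I_raw - I_dark) / (I_white - I_dark),

applied element-wise per band.  Quality assurance checks that reflectance
stays below 1 (no over-exposure relative to the white standard) and reports
the fraction of skin pixels inside the well-exposed 0.3-0.7 window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferenceFrames",
    "QAReport",
    "FormatError",
    "read_envi",
    "write_envi",
    "normalize_reflectance",
    "qa_reflectance",
]


class FormatError(ValueError):
    """Raised when an ENVI header/binary pair is inconsistent or incomplete."""


@dataclass
class SpectralCube:
    """3D spectral image: ``values[row, col, band]`` plus a wavelength axis.

    ``kind`` is ``"raw"`` (camera counts / radiance) or ``"reflectance"``.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"bands ({self.values.shape[2]}) != wavelengths "
                f"({self.wavelengths_nm.size})"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


@dataclass
class ReferenceFrames:
    """White-standard and dark-current frames.

    Either 2D ``(cols, bands)`` line-scan references broadcast across rows,
    or full ``(rows, cols, bands)`` cubes; white and dark must share a shape.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim not in (2, 3):
            raise ValueError("reference frames must be 2D (line) or 3D (cube)")
        usable = np.mean(self.white > self.dark)
        if usable < 0.99:
            raise ValueError(
                f"white > dark on only {usable:.1%} of pixels; references unusable"
            )


@dataclass
class QAReport:
    """Reflectance quality summary over the skin mask."""

    saturation_fraction: float
    fraction_above_one: float
    fraction_in_0_3_0_7: float
    degenerate_fraction: float
    passed: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

# ENVI dtype codes <-> numpy
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_NUMPY_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header grammar."""
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
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


def write_envi(cube: SpectralCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as an ENVI header (``<path>.hdr``) + raw binary pair."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    values = cube.values
    dtype = np.dtype(values.dtype)
    if dtype not in _NUMPY_TO_ENVI:
        values = values.astype(np.float32)
        dtype = np.dtype(np.float32)
    rows, cols, bands = values.shape
    if interleave == "bip":
        ordered = values  # (rows, cols, bands)
    elif interleave == "bil":
        ordered = np.transpose(values, (0, 2, 1))  # (rows, bands, cols)
    else:
        ordered = np.transpose(values, (2, 0, 1))  # (bands, rows, cols)
    np.ascontiguousarray(ordered).tofile(path)
    wl = ", ".join(f"{w:.3f}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        f"description = {{{cube.metadata.get('description', 'hsilesion cube')}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_NUMPY_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"cube kind = {cube.kind}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)


def read_envi(path: str | Path) -> SpectralCube:
    """Read an ENVI header+binary pair written by any BSQ/BIL/BIP writer."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise FormatError(f"ENVI header missing field {required!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("big-endian ENVI files are not supported")
    interleave = fields["interleave"].lower()
    offset = int(fields.get("header offset", "0"))
    data = np.fromfile(path, dtype=_ENVI_DTYPES[dtype_code], offset=offset)
    if data.size != rows * cols * bands:
        raise FormatError(
            f"binary size {data.size} does not match header "
            f"lines*samples*bands = {rows * cols * bands} (field 'bands'?)"
        )
    if interleave == "bip":
        values = data.reshape(rows, cols, bands)
    elif interleave == "bil":
        values = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        values = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if "wavelength" in fields:
        wavelengths = np.array(
            [float(w) for w in fields["wavelength"].split(",")], dtype=float
        )
        if wavelengths.size != bands:
            raise FormatError("field 'wavelength' length does not match 'bands'")
    else:
        wavelengths = np.arange(bands, dtype=float)
    return SpectralCube(
        values=np.ascontiguousarray(values),
        wavelengths_nm=wavelengths,
        kind=fields.get("cube kind", "raw"),
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Reflectance normalization and QA
# ---------------------------------------------------------------------------


def normalize_reflectance(raw: SpectralCube, refs: ReferenceFrames) -> SpectralCube:
    """Convert raw counts to reflectance: R = (raw - dark)/(white - dark).

    Degenerate denominators (white == dark) become NaN and are counted; a
    warning is emitted above 1% degenerate pixels and an error raised if all
    pixels are degenerate.
    """
    if raw.kind != "raw":
        raise ValueError("normalize_reflectance expects a raw cube")
    white, dark = refs.white, refs.dark
    if white.ndim == 2:  # line-scan reference, broadcast across rows
        if white.shape != raw.values.shape[1:]:
            raise ValueError("line reference shape must be (cols, bands)")
        white = white[None, :, :]
        dark = dark[None, :, :]
    elif white.shape != raw.values.shape:
        raise ValueError("full reference frames must match the cube shape")
    denom = white - dark
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.values.astype(float) - dark) / np.where(degenerate, np.nan, denom)
    degenerate_fraction = float(np.mean(np.broadcast_to(degenerate, raw.values.shape)))
    if degenerate_fraction >= 1.0:
        raise ValueError("all reference denominators are degenerate (white == dark)")
    if degenerate_fraction > 0.01:
        warnings.warn(
            f"{degenerate_fraction:.1%} of pixels have white == dark; "
            "set to missing",
            stacklevel=2,
        )
    meta = dict(raw.metadata)
    meta["degenerate_fraction"] = degenerate_fraction
    return SpectralCube(
        values=refl, wavelengths_nm=raw.wavelengths_nm, kind="reflectance",
        metadata=meta,
    )


def qa_reflectance(
    cube: SpectralCube,
    skin_mask: np.ndarray | None = None,
    max_above_one: float = 0.01,
) -> QAReport:
    """Check reflectance plausibility over skin pixels.

    Reflectance against a white standard must stay below 1; well-exposed skin
    sits mostly in the 0.3-0.7 window.  ``passed`` is True when the fraction
    of values >= 1 stays below ``max_above_one``.
    """
    if cube.kind != "reflectance":
        raise ValueError("qa_reflectance expects a reflectance cube")
    if skin_mask is None:
        skin_mask = np.ones(cube.values.shape[:2], dtype=bool)
    skin_mask = np.asarray(skin_mask, dtype=bool)
    if not skin_mask.any():
        raise ValueError("empty skin mask")
    vals = cube.values[skin_mask]
    finite = np.isfinite(vals)
    n = finite.sum()
    if n == 0:
        raise ValueError("no finite reflectance values under the mask")
    v = vals[finite]
    above = float(np.mean(v >= 1.0))
    in_window = float(np.mean((v >= 0.3) & (v <= 0.7)))
    saturated = float(np.mean(v >= 1.0 - 1e-9))
    return QAReport(
        saturation_fraction=saturated,
        fraction_above_one=above,
        fraction_in_0_3_0_7=in_window,
        degenerate_fraction=float(np.mean(~finite)),
        passed=above < max_above_one,
    )
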