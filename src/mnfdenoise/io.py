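"""Hyperspectral cube containers and ENVI / HDF5 input-output.

A cube is a ``W × H × S`` array of absorbance values (``W`` spatial rows,
``H`` spatial columns, ``S`` spectral bands) with a strictly monotone
wavenumber axis in cm⁻¹.  All covariance algebra operates on the flattened
``N × S`` pixel matrix (``N = W·H``), produced by :func:`cube_to_matrix`
with a fixed row-major pixel ordering so that eigenvector signs and
shift-difference noise estimates are reproducible.

On-disk formats:

* **ENVI**: ASCII header (``key = value`` pairs; ``samples``, ``lines``,
  ``bands``, ``data type``, ``interleave``, ``byte order``, optional
  ``wavelength = {…}``) next to a raw binary payload in BSQ, BIL or BIP
  band interleave.  Supported numeric types are 16-bit int (type 2,
  promoted to float on read), 32-bit float (type 4) and 64-bit float
  (type 5).
* **HDF5**: a single dataset ``"cube"`` of shape ``W × H × S`` with an
  attribute ``"wavenumbers"``; used where lossless float round-trips of
  the wavenumber axis matter (ENVI wavelength lists are decimal text).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "HSICube",
    "PixelMatrix",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "read_hdf5",
    "write_hdf5",
    "cube_to_matrix",
    "matrix_to_cube",
]

#: ENVI "data type" codes we read/write, mapped to numpy dtypes.
ENVI_DTYPES = {2: np.dtype("int16"), 4: np.dtype("float32"), 5: np.dtype("float64")}
_DTYPE_CODES = {v: k for k, v in ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


class EnviFormatError(ValueError):
    """Malformed or unsupported ENVI header / payload."""


@dataclass
class HSICube:
    """A ``W × H × S`` absorbance cube with its wavenumber axis.

    Parameters
    ----------
    data
        3-D float array, shape ``(W, H, S)``; axis 0 indexes spatial rows,
        axis 1 spatial columns, axis 2 spectral bands.  Values are
        absorbance in arbitrary units.
    wavenumbers
        Length-``S`` strictly monotone vector in cm⁻¹ (ascending or
        descending).
    interleave_origin
        Interleave of the source file (``"bsq"``/``"bil"``/``"bip"``), or
        ``"memory"`` for cubes born in memory.
    metadata
        Free-form key/value map (description, pixel size, ...).
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    interleave_origin: str = "memory"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        w, h, s = self.data.shape
        if w < 1 or h < 1 or s < 2:
            raise ValueError(f"cube needs W>=1, H>=1, S>=2; got {self.data.shape}")
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.wavenumbers.shape != (s,):
            raise ValueError(
                f"wavenumbers length {self.wavenumbers.size} != band count {s}"
            )
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite absorbance values")

    @property
    def width(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, i: int) -> np.ndarray:
        """Spatial image of band ``i`` (a ``W × H`` view)."""
        return self.data[:, :, i]


@dataclass
class PixelMatrix:
    """The ``N × S`` reshaped view of a cube (``N = W·H`` pixels).

    Row ``j`` is the spectrum of pixel ``j``; column ``i`` is the
    flattened image of band ``i``.  Pixel ordering is row-major over
    (spatial row, spatial column) and is exactly inverted by
    :func:`matrix_to_cube`.
    """

    Y: np.ndarray
    width: int
    height: int
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("pixel matrix must be 2-D")
        if self.Y.shape[0] != self.width * self.height:
            raise ValueError(
                f"N={self.Y.shape[0]} != width*height={self.width * self.height}"
            )
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.wavenumbers.shape != (self.Y.shape[1],):
            raise ValueError("wavenumbers length must equal the band count")

    @property
    def n_pixels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_bands(self) -> int:
        return self.Y.shape[1]

    def band_image(self, i: int) -> np.ndarray:
        """Column ``i`` reshaped back to the ``W × H`` spatial image."""
        return self.Y[:, i].reshape(self.width, self.height)


def cube_to_matrix(cube: HSICube) -> PixelMatrix:
    """Flatten a cube to its ``N × S`` pixel matrix (row-major pixels)."""
    w, h, s = cube.shape
    return PixelMatrix(
        Y=cube.data.reshape(w * h, s),
        width=w,
        height=h,
        wavenumbers=cube.wavenumbers,
    )


def matrix_to_cube(pm: PixelMatrix, metadata: dict | None = None) -> HSICube:
    """Exact inverse of :func:`cube_to_matrix`."""
    return HSICube(
        data=pm.Y.reshape(pm.width, pm.height, pm.n_bands),
        wavenumbers=pm.wavenumbers,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# ENVI


def _binary_path_for(header_path: str) -> str:
    stem = header_path[:-4] if header_path.lower().endswith(".hdr") else header_path
    for cand in (stem, stem + ".img", stem + ".raw", stem + ".dat"):
        if cand != header_path and os.path.exists(cand):
            return cand
    raise EnviFormatError(f"no binary payload found next to header {header_path!r}")


def _parse_envi_header(header_path: str) -> dict:
    with open(header_path, "r") as fh:
        text = fh.read()
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError(f"{header_path!r} does not start with the ENVI magic")
    # Fold brace-delimited multi-line values ({...}) onto one line.
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text, flags=re.S
    )
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _require_int(fields: dict, key: str, header_path: str) -> int:
    if key not in fields:
        raise EnviFormatError(f"header {header_path!r} is missing key {key!r}")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise EnviFormatError(
            f"header key {key!r} has non-integer value {fields[key]!r}"
        ) from exc


def read_envi(header_path: str) -> HSICube:
    """Read an ENVI header + binary pair into a canonical ``W × H × S`` cube.

    The on-disk interleave (BSQ / BIL / BIP) and byte order are resolved so
    that the in-memory layout is always ``(lines, samples, bands)``.

    Raises
    ------
    EnviFormatError
        On a missing/malformed header key, unsupported data type or a
        binary payload whose size disagrees with the declared dimensions.
    """
    fields = _parse_envi_header(header_path)
    samples = _require_int(fields, "samples", header_path)
    lines = _require_int(fields, "lines", header_path)
    bands = _require_int(fields, "bands", header_path)
    dtype_code = _require_int(fields, "data type", header_path)
    if dtype_code not in ENVI_DTYPES:
        raise EnviFormatError(
            f"unsupported ENVI data type {dtype_code} (supported: 2, 4, 5)"
        )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    byte_order = _require_int(fields, "byte order", header_path) if "byte order" in fields else 0
    offset = int(fields.get("header offset", 0))

    dtype = ENVI_DTYPES[dtype_code].newbyteorder(">" if byte_order == 1 else "<")
    binary_path = _binary_path_for(header_path)
    raw = np.fromfile(binary_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"binary {binary_path!r} holds {raw.size} values; header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    data = np.ascontiguousarray(data, dtype=np.float64)

    if "wavelength" in fields:
        wn = np.array(
            [float(tok) for tok in fields["wavelength"].strip("{} \t").split(",") if tok.strip()]
        )
        if wn.size != bands:
            raise EnviFormatError("wavelength list length disagrees with band count")
    else:
        wn = np.arange(bands, dtype=float)

    metadata = {k: v for k, v in fields.items() if k == "description"}
    return HSICube(data=data, wavenumbers=wn, interleave_origin=interleave, metadata=metadata)


def write_envi(cube: HSICube, header_path: str, interleave: str = "bsq") -> None:
    """Write a cube as an ENVI header (``.hdr``) + float64 binary pair.

    ``read_envi`` inverts this exactly for float64 payloads.  The binary is
    written next to the header with the ``.hdr`` suffix stripped and
    ``.img`` appended.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}, got {interleave!r}")
    w, h, s = cube.shape
    data = np.asarray(cube.data, dtype=np.float64)
    if interleave == "bsq":
        payload = data.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = data.transpose(0, 2, 1)
    else:
        payload = data

    stem = header_path[:-4] if header_path.lower().endswith(".hdr") else header_path
    binary_path = stem + ".img"

    wn_text = ", ".join(repr(float(v)) for v in cube.wavenumbers)
    desc = cube.metadata.get("description", "mnfdenoise export")
    header = (
        "ENVI\n"
        f"description = {{{desc}}}\n"
        f"samples = {h}\n"
        f"lines = {w}\n"
        f"bands = {s}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype('float64')]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{{wn_text}}}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    np.ascontiguousarray(payload).tofile(binary_path)


# ---------------------------------------------------------------------------
# HDF5


def write_hdf5(cube: HSICube, path: str) -> None:
    """Store a cube as HDF5: dataset ``"cube"`` + attribute ``"wavenumbers"``."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("cube", data=cube.data)
        ds.attrs["wavenumbers"] = cube.wavenumbers


def read_hdf5(path: str) -> HSICube:
    """Read a cube written by :func:`write_hdf5` (lossless float round-trip)."""
    with h5py.File(path, "r") as fh:
        if "cube" not in fh:
            raise EnviFormatError(f"{path!r} has no dataset 'cube'")
        ds = fh["cube"]
        data = ds[()]
        wn = np.asarray(ds.attrs["wavenumbers"])
    return HSICube(data=data, wavenumbers=wn)
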