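"""Minimal ENVI-format reader/writer for hyperspectral cubes.

ENVI stores a cube as a flat binary raster plus a small text header (``.hdr``)
declaring ``samples`` (columns), ``lines`` (rows), ``bands``, the byte
``interleave`` (BSQ/BIL/BIP), a numeric ``data type`` code and, for
spectrometer output, the band-center ``wavelength`` list.  Only the numeric
dtypes produced by NIR line-scan instruments are supported.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .cube import ReferenceFrame, SpectralCube

# ENVI "data type" codes -> numpy dtypes (little-endian by default)
_DTYPE_BY_CODE = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_CODE_BY_KIND = {np.dtype(k): c for c, k in _DTYPE_BY_CODE.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def _header_path(path: Path) -> Path:
    for cand in (path.with_suffix(path.suffix + ".hdr"), path.with_suffix(".hdr")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"no ENVI header found for {path}")


def _parse_header(text: str) -> dict[str, str]:
    """Parse ``key = value`` pairs; brace-enclosed values may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    # join brace blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_float_list(value: str) -> np.ndarray:
    inner = value.strip().lstrip("{").rstrip("}")
    return np.array([float(tok) for tok in inner.replace(",", " ").split()])


def _read_raster(path: Path) -> tuple[np.ndarray, dict[str, str]]:
    header = _parse_header(_header_path(path).read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in header:
            raise ValueError(f"ENVI header missing required key '{key}'")
    cols = int(header["samples"])
    rows = int(header["lines"])
    bands = int(header["bands"])
    interleave = header["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    code = int(header["data type"])
    if code not in _DTYPE_BY_CODE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = _DTYPE_BY_CODE[code]
    if int(header.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(path, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"raster holds {raw.size} values but header declares {expected} "
            f"({rows} lines x {cols} samples x {bands} bands)"
        )
    if interleave == "bsq":  # (bands, rows, cols)
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":  # (rows, bands, cols)
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip: (rows, cols, bands)
        data = raw.reshape(rows, cols, bands)
    return np.ascontiguousarray(data), header


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI cube into row x col x band order, wavelengths from header."""
    path = Path(path)
    data, header = _read_raster(path)
    if "wavelength" not in header:
        raise ValueError("ENVI header missing required key 'wavelength'")
    wavelengths = _parse_float_list(header["wavelength"])
    if len(wavelengths) != data.shape[2]:
        raise ValueError(
            f"header lists {len(wavelengths)} wavelengths but raster has "
            f"{data.shape[2]} bands"
        )
    kind = header.get("pelletchem kind", "raw").strip().lower()
    kind = kind if kind in ("raw", "calibrated") else "raw"
    return SpectralCube(data, wavelengths, kind=kind)


def read_reference(path: str | Path, role: str) -> ReferenceFrame:
    """Read a white/dark reference recorded as an ENVI raster."""
    data, _ = _read_raster(Path(path))
    if data.shape[0] == 1:  # single-line recording -> cols x bands
        data = data[0]
    return ReferenceFrame(data, role)


def write_cube(
    cube: SpectralCube,
    path: str | Path,
    *,
    interleave: str = "bil",
) -> None:
    """Write a cube as ENVI raster + header (wavelengths included)."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    dtype = data.dtype
    if dtype not in _CODE_BY_KIND:
        data = data.astype("<f8")
        dtype = data.dtype
    rows, cols, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_BY_KIND[np.dtype(dtype.newbyteorder('<'))]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pelletchem kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)


def write_reference(frame: ReferenceFrame, path: str | Path) -> None:
    """Write a reference frame as a single-line (or multi-line) ENVI raster."""
    data = frame.data
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    cube = SpectralCube(
        data, np.arange(1.0, data.shape[2] + 1.0), kind="raw"
    )
    write_cube(cube, path)
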