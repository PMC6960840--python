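"""ENVI-style hyperspectral cube and label-map I/O.

Supports a pragmatic subset of the ENVI dialect: flat binary cubes
(BSQ/BIL/BIP interleave) described by a ``.hdr`` text header, data types
1 (uint8), 2 (int16), 4 (float32) and 12 (uint16), with the byte-order
field honored.  In memory every cube is a ``(rows, cols, bands)`` array
regardless of file interleave; coordinates are 0-based ``(row, col)``.

Label maps use integer class codes with 0 reserved for unlabeled /
background pixels.  They can be stored either as a whitespace-delimited
integer grid (text) or as a 1-band ENVI classification raster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# ENVI "data type" codes -> numpy dtype characters (byte order prepended).
_ENVI_DTYPES = {1: "u1", 2: "i2", 4: "f4", 12: "u2"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_KNOWN_KEYS = {
    "description", "samples", "lines", "bands", "header offset",
    "file type", "data type", "interleave", "byte order", "wavelength",
    "wavelength units", "classes", "class names", "sensor type",
    "class lookup", "band names",
}


class EnviFormatError(ValueError):
    """Raised for malformed or unsupported ENVI header/binary pairs."""


@dataclass
class HsiCube:
    """A hyperspectral cube: reflectance indexed ``(row, col, band)``.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Pixel spectra, band axis last.
    wavelengths : ndarray or None
        Optional per-band centers in nm, strictly increasing.
    """

    data: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        rows, cols, bands = self.data.shape
        if rows < 1 or cols < 1 or bands < 1:
            raise ValueError(f"degenerate cube shape {self.data.shape}")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (bands,):
                raise ValueError("wavelengths length must equal band count")
            if not np.all(np.diff(self.wavelengths) > 0):
                raise ValueError("wavelengths must be strictly increasing")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """All spectra as a ``(rows*cols, bands)`` row-major view."""
        return self.data.reshape(-1, self.bands)


@dataclass
class LabelMap:
    """Integer class code per pixel; 0 means unlabeled/background."""

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D (rows, cols)")
        present = set(np.unique(self.labels)) - {0}
        if not self.class_names:
            self.class_names = {int(c): f"class_{int(c)}" for c in sorted(present)}
        missing = present - set(self.class_names)
        if missing:
            raise ValueError(f"codes without names: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def codes(self) -> list[int]:
        """Nonzero class codes present, ascending."""
        return [int(c) for c in np.unique(self.labels) if c != 0]


def _parse_header(header_path: Path) -> dict[str, str]:
    text = header_path.read_text()
    lines = iter(text.splitlines())
    first = next(lines, "")
    fields: dict[str, str] = {}
    if first.strip() != "ENVI":
        # tolerate headers missing the magic line: re-parse from the top
        lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            for cont in lines:
                parts.append(cont.strip())
                if cont.strip().endswith("}"):
                    break
            value = " ".join(parts)
        if key not in _KNOWN_KEYS:
            logger.warning("ignoring unknown ENVI header key %r", key)
            continue
        fields[key] = value
    return fields


def _brace_list(value: str) -> list[str]:
    return [v.strip() for v in value.strip().lstrip("{").rstrip("}").split(",") if v.strip()]


def _find_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".img"), stem.with_suffix(".dat"),
                 stem.with_suffix(".bsq"), stem.with_suffix(".bil"),
                 stem.with_suffix(".bip"), stem):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary companion found for {header_path}")


def _read_raw(header_path: Path) -> tuple[np.ndarray, dict[str, str]]:
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path)
    for req in ("samples", "lines", "bands", "data type"):
        if req not in fields:
            raise EnviFormatError(f"header missing required key {req!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {code}")
    order = ">" if int(fields.get("byte order", "0")) == 1 else "<"
    dtype = np.dtype(order + _ENVI_DTYPES[code])
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    offset = int(fields.get("header offset", "0"))

    binary = _find_binary(header_path)
    raw = np.fromfile(binary, dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"{binary}: binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(rows, cols, bands)
    # native byte order in memory
    return np.ascontiguousarray(data.astype(dtype.newbyteorder("="))), fields


def read_envi(header_path: str | Path) -> HsiCube:
    """Read an ENVI header/binary pair into a ``(row, col, band)`` cube."""
    data, fields = _read_raw(Path(header_path))
    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(v) for v in _brace_list(fields["wavelength"])])
    return HsiCube(data=data, wavelengths=wavelengths)


def write_envi(
    cube: HsiCube,
    header_path: str | Path,
    interleave: str = "bsq",
    byte_order: int = 0,
) -> None:
    """Write ``cube`` as an ENVI header (.hdr) + flat binary (.img) pair.

    Integer payloads round-trip bit-exactly; float payloads are stored as
    float32 (ENVI data type 4).
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        if np.issubdtype(dtype, np.floating):
            dtype = np.dtype("f4")
        elif np.issubdtype(dtype, np.integer):
            dtype = np.dtype("i2")
        else:
            raise EnviFormatError(f"cannot store dtype {dtype}")
    code = _DTYPE_CODES[dtype]
    order = ">" if byte_order == 1 else "<"
    out = cube.data.astype(dtype.newbyteorder(order))

    if interleave == "bsq":
        flat = out.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = out.transpose(0, 2, 1)
    else:
        flat = out
    binary_path = header_path.with_suffix(".img")
    flat.tofile(binary_path)

    lines = [
        "ENVI",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        f"byte order = {byte_order}",
    ]
    if cube.wavelengths is not None:
        wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
        lines.append("wavelength = {" + wl + "}")
    header_path.write_text("\n".join(lines) + "\n")


def write_envi_classification(map_: LabelMap, header_path: str | Path) -> None:
    """Write a label map as a 1-band ENVI classification raster."""
    header_path = Path(header_path)
    labels = map_.labels
    if labels.max(initial=0) > np.iinfo("u1").max:
        dtype, code = np.dtype("<u2"), 12
    else:
        dtype, code = np.dtype("u1"), 1
    labels.astype(dtype).tofile(header_path.with_suffix(".img"))
    codes = map_.codes()
    names = ", ".join(["Unclassified"] + [map_.class_names[c] for c in codes])
    lines = [
        "ENVI",
        f"samples = {labels.shape[1]}",
        f"lines = {labels.shape[0]}",
        "bands = 1",
        "header offset = 0",
        "file type = ENVI Classification",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        f"classes = {len(codes) + 1}",
        "class names = {" + names + "}",
    ]
    header_path.write_text("\n".join(lines) + "\n")


def read_envi_classification(header_path: str | Path) -> LabelMap:
    """Read an ENVI classification raster written by this package."""
    data, fields = _read_raw(Path(header_path))
    labels = data[:, :, 0].astype(int)
    class_names: dict[int, str] = {}
    if "class names" in fields:
        names = _brace_list(fields["class names"])
        # entry 0 is the unclassified placeholder
        class_names = {i: n for i, n in enumerate(names) if i > 0}
        present = set(np.unique(labels)) - {0}
        class_names = {c: n for c, n in class_names.items() if c in present} or {
            int(c): f"class_{int(c)}" for c in sorted(present)
        }
    return LabelMap(labels=labels, class_names=class_names)


def write_label_grid(map_: LabelMap, path: str | Path) -> None:
    """Write labels as a whitespace-delimited integer grid text file."""
    np.savetxt(path, map_.labels, fmt="%d")


def read_label_grid(path: str | Path, class_names: dict[int, str] | None = None) -> LabelMap:
    """Read a whitespace-delimited integer grid as a label map."""
    labels = np.atleast_2d(np.loadtxt(path, dtype=int))
    return LabelMap(labels=labels, class_names=class_names or {})


def extract_pixels(cube: HsiCube, map_: LabelMap, class_code: int) -> np.ndarray:
    """Spectra of exactly the pixels carrying ``class_code``, row-major.

    Returns an ``(n, bands)`` array (possibly empty).
    """
    if map_.shape != (cube.rows, cube.cols):
        raise ValueError(
            f"label map shape {map_.shape} != cube shape {(cube.rows, cube.cols)}"
        )
    if class_code != 0 and class_code not in map_.class_names:
        if class_code not in np.unique(map_.labels):
            # unknown code with no pixels: empty result is still meaningful
            warnings.warn(f"class code {class_code} absent from label map")
    mask = (map_.labels == class_code).reshape(-1)
    return cube.pixels()[mask].astype(float)
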