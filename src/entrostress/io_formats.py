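"""Readers and writers for the imaging and tabular formats the pipeline touches.

Hyperspectral cubes travel as ENVI BSQ pairs (a plain-text ``.hdr`` next to a
raw binary payload) — the dialect Specim-style cameras export — or as a
single-file ``.npz`` with embedded shape and wavelengths, which is convenient
for programmatic fixtures.  Grayscale images are single-channel TIFF or a
plain-text matrix; every table is CSV.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

FEATURE_NAMES = ("min", "max", "mean", "std", "max_min", "entropy")

# ENVI numeric codes for the dtypes we read/write
_ENVI_DTYPES = {2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A reflectance cube: ``data[row, col, channel]`` with per-channel wavelengths in nm."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"cube must be 3-D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValidationError(f"cube dimensions must be >= 1, got {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValidationError(
                f"wavelength count {len(self.wavelengths)} != channel count {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, :, i]


@dataclass
class GrayImage:
    """A single-channel float image.  Invalid pixels are flagged as NaN.

    ``kind`` distinguishes thermal images ("TIR"), computed vegetation indices
    ("index") and raw cube channels ("channel"); downstream trimming defaults
    depend on it.
    """

    data: np.ndarray
    kind: str = "index"
    name: str = ""

    _KINDS = ("TIR", "index", "channel")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or any(s < 1 for s in self.data.shape):
            raise ValidationError(f"image must be 2-D and non-empty, got shape {self.data.shape}")
        if self.kind not in self._KINDS:
            raise ValidationError(f"kind must be one of {self._KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean image of pixels carrying a usable value."""
        return np.isfinite(self.data)


@dataclass
class FeatureTable:
    """Long-format table of histogram statistics.

    One row per (sample, index, feature); ``day_label`` is the key-day integer
    the sample was acquired on.
    """

    frame: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    COLUMNS = ("sample_id", "day_label", "index_name", "feature_name", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(self.frame):
            key = self.frame[["sample_id", "index_name", "feature_name"]]
            if key.duplicated().any():
                raise ValidationError("(sample_id, index_name, feature_name) must be unique")
            bad = set(self.frame["feature_name"]) - set(FEATURE_NAMES)
            if bad:
                raise ValidationError(f"unknown feature names {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def days(self) -> list[int]:
        return sorted(self.frame["day_label"].unique())

    def to_matrix(self, subset: Iterable[tuple[str, str]] | None = None):
        """Pivot to (samples × features) for classifier input.

        Returns ``(X, y, columns)`` where columns are ``(index_name,
        feature_name)`` pairs in the order requested (or sorted, if ``subset``
        is None) and ``y`` is the per-sample day label.
        """
        wide = self.frame.pivot_table(
            index=["sample_id", "day_label"],
            columns=["index_name", "feature_name"],
            values="value",
            sort=True,
        )
        cols = list(subset) if subset is not None else sorted(wide.columns)
        missing = [c for c in cols if tuple(c) not in set(map(tuple, wide.columns))]
        if missing:
            raise ValidationError(f"requested features absent from table: {missing}")
        wide = wide.loc[:, [tuple(c) for c in cols]].sort_index()
        X = wide.to_numpy(dtype=float)
        y = np.array([day for (_sid, day) in wide.index], dtype=int)
        return X, y, cols


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "day_label": pd.Series(dtype=int),
            "index_name": pd.Series(dtype=str),
            "feature_name": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# ENVI cube I/O


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` grammar of an ENVI header."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # braced values may span lines; normalize them first
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val.strip("{}").strip()
        fields[key] = val
    return fields


def write_cube(cube: HyperCube, path: str | os.PathLike) -> None:
    """Write a cube.

    ``*.npz`` → single-file numpy archive with ``data`` and ``wavelengths``;
    anything else → ENVI BSQ pair ``path`` (raw) + ``path + '.hdr'``.
    """
    path = os.fspath(path)
    if path.endswith(".npz"):
        np.savez(path, data=cube.data, wavelengths=cube.wavelengths)
        return
    rows, cols, bands = cube.shape
    dtype = cube.data.dtype if cube.data.dtype in _DTYPE_CODES else np.dtype(np.float64)
    code = _DTYPE_CODES[np.dtype(dtype)]
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(header)
    # BSQ: band-sequential, band-major on disk
    np.ascontiguousarray(np.transpose(cube.data.astype(dtype), (2, 0, 1))).tofile(path)


def read_cube(path: str | os.PathLike) -> HyperCube:
    """Read a cube written by :func:`write_cube` (ENVI BSQ pair or ``.npz``)."""
    path = os.fspath(path)
    if path.endswith(".npz"):
        if not os.path.exists(path):
            raise FormatError(f"no such cube file: {path}")
        with np.load(path) as z:
            if "data" not in z or "wavelengths" not in z:
                raise FormatError(f"{path}: missing 'data'/'wavelengths' arrays")
            return HyperCube(z["data"], z["wavelengths"])
    hdr_path = path + ".hdr" if os.path.exists(path + ".hdr") else os.path.splitext(path)[0] + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"missing ENVI header for {path}")
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{hdr_path}: incomplete or corrupt header ({exc})") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{hdr_path}: only BSQ interleave is supported")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    offset = int(fields.get("header offset", 0))
    expected = rows * cols * bands * dtype.itemsize
    actual = os.path.getsize(path) - offset
    if actual != expected:
        raise ValidationError(
            f"{path}: payload is {actual} bytes but header declares "
            f"{rows}x{cols}x{bands} {dtype.name} = {expected} bytes"
        )
    raw = np.fromfile(path, dtype=dtype, count=rows * cols * bands, offset=offset)
    data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path}: no wavelength block")
    wavelengths = np.array([float(t) for t in fields["wavelength"].replace(",", " ").split()])
    if len(wavelengths) != bands:
        raise ValidationError(
            f"{hdr_path}: {len(wavelengths)} wavelengths for {bands} bands"
        )
    return HyperCube(data, wavelengths)


# ---------------------------------------------------------------------------
# Grayscale image I/O


def write_gray_image(img: GrayImage, path: str | os.PathLike) -> None:
    """TIFF for ``.tif``/``.tiff`` paths, plain-text matrix otherwise."""
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img.data.astype(np.float64))
    else:
        np.savetxt(path, img.data, fmt="%.17g")


def read_gray_image(path: str | os.PathLike, kind: str = "index", name: str = "") -> GrayImage:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such image file: {path}")
    if path.endswith((".tif", ".tiff")):
        data = np.asarray(tifffile.imread(path), dtype=float)
    else:
        data = np.atleast_2d(np.loadtxt(path, dtype=float))
    return GrayImage(data, kind=kind, name=name or os.path.basename(path))


def write_mask_image(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Boolean mask as a 0/1 uint8 TIFF."""
    tifffile.imwrite(os.fspath(path), np.asarray(mask, dtype=np.uint8))


def read_mask_image(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(os.fspath(path))) != 0


# ---------------------------------------------------------------------------
# Feature-table CSV I/O


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """CSV with a header row; floats carry 17 significant digits (lossless round-trip)."""
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such feature table: {path}")
    frame = pd.read_csv(
        path,
        dtype={
            "sample_id": str,
            "day_label": int,
            "index_name": str,
            "feature_name": str,
            "value": float,
        },
    )
    return FeatureTable(frame)
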