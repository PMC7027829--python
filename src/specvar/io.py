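"""File I/O: ENVI cubes, TIFF maps, delimited feature tables, YAML configs.

ENVI support covers the plain header (.hdr) + flat-binary pair with BSQ, BIL
or BIP interleaves and the common data-type codes, reading wavelengths from
the header ``wavelength`` field. TIFF cubes are read/written with tifffile,
with wavelengths in a sidecar CSV (``band_index,wavelength_nm``) since TIFF
has no wavelength tag. Feature tables are plain delimited text with header
``row,col,community,f1..fp``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .cube import SpectralCube
from .errors import ParameterError, ValidationError
from .features import FeatureMatrix
from .partition import CommunityGrid

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> Dict[str, str]:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValidationError("not an ENVI header (missing ENVI magic line)")
    # join brace-delimited multi-line values, then split on '='
    fields: Dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(
        r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL
    )
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip() if val.endswith("}") else val[1:].strip()
        fields[key] = val
    return fields


def read_envi(header_path: Union[str, Path]) -> SpectralCube:
    """Read an ENVI .hdr / flat-binary pair into a SpectralCube.

    The data file is located by replacing the ``.hdr`` suffix (or appending
    none); ``samples``, ``lines``, ``bands``, ``interleave``, ``data type``
    and ``wavelength`` header fields are honoured, plus ``map info`` for the
    geotransform and ``data ignore value`` for nodata.
    """
    header_path = Path(header_path)
    hdr = _parse_envi_header(header_path.read_text())
    for key in ("samples", "lines", "bands"):
        if key not in hdr:
            raise ValidationError(f"ENVI header missing required field {key!r}")
    samples = int(hdr["samples"])  # cols
    lines = int(hdr["lines"])  # rows
    bands = int(hdr["bands"])
    interleave = hdr.get("interleave", "bsq").lower()
    code = int(hdr.get("data type", 4))
    if code not in _ENVI_DTYPES:
        raise ValidationError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")

    data_path = header_path.with_suffix("")
    for cand in (data_path, header_path.with_suffix(".dat"),
                 header_path.with_suffix(".img")):
        if cand.exists() and cand != header_path:
            data_path = cand
            break
    else:
        raise ValidationError(f"no data file found for header {header_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValidationError(
            f"ENVI data file holds {raw.size} values, expected {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValidationError(f"unsupported interleave {interleave!r}")

    if "wavelength" in hdr:
        wavelengths = np.array(
            [float(x) for x in hdr["wavelength"].replace("\n", " ").split(",")]
        )
    else:
        wavelengths = np.arange(bands, dtype=float)

    geotransform = None
    if "map info" in hdr:
        parts = [p.strip() for p in hdr["map info"].split(",")]
        try:
            px, py = float(parts[3]), float(parts[4])
            dx, dy = float(parts[5]), float(parts[6])
            geotransform = (px, dx, 0.0, py, 0.0, -dy)
        except (IndexError, ValueError):
            pass

    nodata = float(hdr["data ignore value"]) if "data ignore value" in hdr else None
    return SpectralCube(
        reflectance=cube.astype(float),
        wavelengths=wavelengths,
        geotransform=geotransform,
        nodata_value=nodata,
    )


def write_envi(
    cube: SpectralCube,
    header_path: Union[str, Path],
    interleave: str = "bsq",
    dtype: np.dtype = np.float32,
) -> None:
    """Write a SpectralCube as an ENVI .hdr + .dat pair."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".dat")
    rows, cols, bands = cube.reflectance.shape
    arr = cube.reflectance.astype(dtype)
    interleave = interleave.lower()
    if interleave == "bsq":
        arr.transpose(2, 0, 1).tofile(data_path)
    elif interleave == "bil":
        arr.transpose(0, 2, 1).tofile(data_path)
    elif interleave == "bip":
        arr.tofile(data_path)
    else:
        raise ParameterError(f"unsupported interleave {interleave!r}")
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {specvar export}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    if cube.geotransform is not None:
        x0, dx, _, y0, _, dy = cube.geotransform
        lines.append(
            "map info = {Arbitrary, 1, 1, "
            f"{x0:g}, {y0:g}, {dx:g}, {abs(dy):g}, units=Meters}}"
        )
    header_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TIFF cubes and maps
# ---------------------------------------------------------------------------

def read_tiff_cube(
    path: Union[str, Path],
    wavelengths: Optional[np.ndarray] = None,
    wavelength_csv: Optional[Union[str, Path]] = None,
) -> SpectralCube:
    """Read a multi-band TIFF as a cube; wavelengths from a sidecar CSV.

    The sidecar has columns ``band_index,wavelength_nm`` (0-based indices).
    With neither wavelengths nor sidecar given, ``<path>.wavelengths.csv`` is
    tried, else band indices are used.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif axes.endswith("S"):  # (rows, cols, samples) contiguous
        pass
    else:  # band-major pages (bands, rows, cols)
        arr = arr.transpose(1, 2, 0)
    if wavelengths is None:
        if wavelength_csv is None:
            cand = path.with_suffix(path.suffix + ".wavelengths.csv")
            wavelength_csv = cand if cand.exists() else None
        if wavelength_csv is not None:
            tbl = pd.read_csv(wavelength_csv)
            wavelengths = tbl.sort_values("band_index")["wavelength_nm"].to_numpy()
        else:
            wavelengths = np.arange(arr.shape[2], dtype=float)
    return SpectralCube(reflectance=arr.astype(float), wavelengths=wavelengths)


def write_tiff(
    array: np.ndarray,
    path: Union[str, Path],
    nodata: float = np.nan,
) -> None:
    """Write a single-band (rows, cols) or stack (rows, cols, k) map as TIFF."""
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)  # band-major pages
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(
    path: Union[str, Path], delimiter: str = ","
) -> Tuple[FeatureMatrix, CommunityGrid]:
    """Read a ``row,col,community,f1..fp`` table into (FeatureMatrix, grid).

    Community labels are re-indexed to 0..q−1 preserving sorted label order.
    Duplicate (row, col) entries and non-numeric features are rejected with
    the offending line number (1-based, counting the header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty feature table") from None
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: parse error: {exc}") from None
    required = ["row", "col", "community"]
    if list(df.columns[:3]) != required:
        raise ValidationError(
            f"{path}: header must start with {','.join(required)}; "
            f"got {','.join(map(str, df.columns[:3]))}"
        )
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: no feature columns present")
    feat_cols = list(df.columns[3:])
    for col in feat_cols + required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = numeric
    dup = df.duplicated(subset=["row", "col"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValidationError(f"{path}: duplicate (row, col) at line {line}")
    labels_raw = df["community"].astype(int).to_numpy()
    uniq = np.unique(labels_raw)
    label_map = {lab: i for i, lab in enumerate(uniq)}
    labels = np.array([label_map[lab] for lab in labels_raw])
    counts = np.bincount(labels)
    m = int(counts[0]) if (counts == counts[0]).all() else None
    Y = FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        feature_labels=[str(c) for c in feat_cols],
        pixel_index=df[["row", "col"]].to_numpy(dtype=int),
    )
    grid = CommunityGrid(assignment=labels, q=uniq.size, m=m)
    return Y, grid


def write_feature_table(
    Y: FeatureMatrix,
    grid: CommunityGrid,
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    """Write a FeatureMatrix + community assignment as a delimited table.

    Numeric features are written with 17 significant digits so a read-back
    reproduces the values exactly.
    """
    df = pd.DataFrame(
        {
            "row": Y.pixel_index[:, 0],
            "col": Y.pixel_index[:, 1],
            "community": grid.assignment,
        }
    )
    for j, label in enumerate(Y.feature_labels):
        df[label] = Y.values[:, j]
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
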