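"""Spectra table CSV I/O, ENVI cube reading, ROI extraction, band trimming."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RoiSpec, SpectraTable, WavelengthGrid

#: Wavelength intervals (nm, closed) removed by default: the low-SNR edges of
#: the visible/NIR acquisition range.
DEFAULT_EXCLUDED_RANGES = ((377.0, 410.0), (980.0, 1019.0))


def read_spectra_csv(path, label_column: str = "label") -> SpectraTable:
    """Read a spectra table from CSV.

    The header holds band-center wavelengths in nm plus a label column (and an
    optional leading ``sample_id`` column); one row per sample.
    """
    df = pd.read_csv(path, dtype={label_column: str}, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"CSV {path} has no {label_column!r} column")
    band_cols = [c for c in df.columns if c not in (label_column, "sample_id")]
    try:
        centers = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength in header of {path}: {exc}") from exc
    if np.any(np.diff(centers) <= 0):
        raise ValueError("grid not increasing")
    matrix = np.empty((len(df), len(band_cols)), dtype=float)
    for j, col in enumerate(band_cols):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(
                f"non-numeric reflectance at row {bad[0]}, column {col!r} in {path}"
            )
        matrix[:, j] = vals
    sample_ids = df["sample_id"].to_numpy() if "sample_id" in df.columns else None
    return SpectraTable(matrix, WavelengthGrid(centers), df[label_column].to_numpy(),
                        sample_ids)


def write_spectra_csv(table: SpectraTable, path, wavelength_decimals: int | None = None) -> None:
    """Write a spectra table as CSV (inverse of :func:`read_spectra_csv`).

    ``wavelength_decimals=None`` writes the grid at full precision so a
    write -> read round trip is exact; pass 2 for the conventional 2-decimal
    header used in external reports.
    """
    if wavelength_decimals is None:
        cols = [repr(float(w)) for w in table.wavelengths]
    else:
        cols = [f"{w:.{wavelength_decimals}f}" for w in table.wavelengths]
    df = pd.DataFrame(table.reflectance, columns=cols)
    df.insert(0, "sample_id", table.sample_ids)
    df["label"] = table.labels
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round trip


def extract_roi_mean(cube: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Mean spectrum of a square ROI of a [rows x cols x bands] reflectance cube.

    Raises if the ROI extends past the cube's spatial extent (no clipping).
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be rows x cols x bands")
    rows, cols, _ = cube.shape
    r1, c1 = roi.row0 + roi.side, roi.col0 + roi.side
    if r1 > rows or c1 > cols:
        raise ValueError(
            f"ROI [{roi.row0}:{r1}, {roi.col0}:{c1}] exceeds cube extent {rows}x{cols}"
        )
    patch = cube[roi.row0:r1, roi.col0:c1, :]
    return patch.mean(axis=(0, 1))


def trim_bands(table: SpectraTable, exclude=DEFAULT_EXCLUDED_RANGES) -> SpectraTable:
    """Drop bands whose center falls inside any closed ``[lo, hi]`` interval.

    Centers equal to an interval endpoint are removed (closed-interval rule).
    """
    keep = np.ones(table.n_bands, dtype=bool)
    for lo, hi in exclude:
        if lo > hi:
            raise ValueError(f"malformed exclusion interval [{lo}, {hi}]")
        keep &= ~((table.wavelengths >= lo) & (table.wavelengths <= hi))
    if not keep.any():
        raise ValueError("all bands excluded")
    return table.take_bands(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# ENVI cubes.  Only reflectance-calibrated cubes are handled; radiometric
# calibration is an upstream (instrument-software) step.

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    # join brace-delimited multi-line values before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(hdr_path) -> tuple[np.ndarray, WavelengthGrid | None]:
    """Read an ENVI cube (.hdr + binary) as a [lines x samples x bands] array.

    Supports bil/bip/bsq interleaves and the common numeric data types.
    Returns the cube and the wavelength grid if the header lists one.
    """
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    data_path = hdr_path.with_suffix("." + interleave)
    if not data_path.exists():
        for ext in (".img", ".dat", ".raw", ""):
            cand = hdr_path.with_suffix(ext)
            if cand.exists() and cand != hdr_path:
                data_path = cand
                break
        else:
            raise FileNotFoundError(f"no ENVI data file next to {hdr_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError("ENVI data size does not match header dimensions")
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    grid = None
    if "wavelength" in fields:
        wl = fields["wavelength"].strip("{} ")
        centers = np.array([float(v) for v in wl.split(",") if v.strip()])
        grid = WavelengthGrid(centers)
    return cube.astype(float), grid


def write_envi(cube: np.ndarray, hdr_path, grid: WavelengthGrid | None = None,
               interleave: str = "bil") -> None:
    """Write a [lines x samples x bands] float32 cube as ENVI .hdr + binary."""
    cube = np.asarray(cube, dtype=np.float32)
    lines, samples, bands = cube.shape
    hdr_path = Path(hdr_path)
    parts = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "data type = 4",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if grid is not None:
        wl = ", ".join(f"{w:.4f}" for w in grid.centers)
        parts.append("wavelength = { " + wl + " }")
    hdr_path.write_text("\n".join(parts) + "\n")
    if interleave == "bsq":
        out = cube.transpose(2, 0, 1)
    elif interleave == "bil":
        out = cube.transpose(0, 2, 1)
    elif interleave == "bip":
        out = cube
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    out.tofile(hdr_path.with_suffix("." + interleave))
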