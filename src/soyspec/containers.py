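"""Core data containers: the wavelength axis and the sample x band spectra table.

A :class:`SpectraTable` is the universal currency of the pipeline: a dense
reflectance matrix (rows = samples, columns = spectral bands), the band-center
wavelengths in nm, one class label per row, and opaque sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default class labels for the soybean-component problem.
CLASS_INTACT = "intact"
CLASS_BROKEN = "broken"
CLASS_IMPURITY = "impurity"
DEFAULT_CLASSES = (CLASS_INTACT, CLASS_BROKEN, CLASS_IMPURITY)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nm."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        # single-band grids arise from feature-selection subsets (k = 1)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("grid needs at least 1 band center")
        if not np.all(np.isfinite(centers)) or np.any(centers <= 0):
            raise ValueError("grid centers must be finite and positive")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("grid not increasing")

    def __len__(self) -> int:
        return int(self.centers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.centers, other.centers)

    def __hash__(self) -> int:
        return hash(self.centers.tobytes())

    @property
    def spacing(self) -> float:
        """Mean spacing between adjacent band centers (nm)."""
        if self.centers.size < 2:
            raise ValueError("spacing undefined for a single-band grid")
        return float(np.mean(np.diff(self.centers)))


def default_grid(n_channels: int = 281, lo: float = 377.0, hi: float = 977.0) -> WavelengthGrid:
    """The default instrument emulation grid: 281 uniform channels, 377-977 nm.

    The spacing (600/280 ~ 2.1429 nm) matches the gap between adjacent band
    centers quoted for the line-scan spectrometer; the true instrument axis is
    nonlinear and not published, so the grid is configurable everywhere.
    """
    return WavelengthGrid(np.linspace(lo, hi, n_channels))


@dataclass
class SpectraTable:
    """Reflectance matrix with wavelength grid, class labels and sample ids."""

    reflectance: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D sample x band matrix")
        n, p = self.reflectance.shape
        if p != len(self.grid):
            raise ValueError(
                f"band count mismatch: matrix has {p} columns, grid has {len(self.grid)}"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal n_samples")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (n,):
                raise ValueError("sample_ids length must equal n_samples")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.centers

    def take_rows(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            self.reflectance[idx], self.grid, self.labels[idx], self.sample_ids[idx]
        )

    def take_bands(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            self.reflectance[:, idx],
            WavelengthGrid(self.grid.centers[idx]),
            self.labels,
            self.sample_ids,
        )

    def with_reflectance(self, matrix: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraTable":
        """Same rows/labels, new reflectance matrix (optionally a new grid)."""
        return SpectraTable(matrix, grid if grid is not None else self.grid,
                            self.labels, self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance,
                          columns=[repr(float(w)) for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "SpectraTable":
        """Build a table from a DataFrame whose numeric column names are wavelengths."""
        if label_column not in df.columns:
            raise ValueError(f"missing label column {label_column!r}")
        labels = df[label_column].to_numpy()
        sample_ids = (
            df["sample_id"].to_numpy() if "sample_id" in df.columns else None
        )
        band_cols = [c for c in df.columns if c not in (label_column, "sample_id")]
        centers = np.array([float(c) for c in band_cols])
        matrix = df[band_cols].to_numpy(dtype=float)
        return cls(matrix, WavelengthGrid(centers), labels, sample_ids)


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest in pixel coordinates (top-left corner + side)."""

    row0: int
    col0: int
    side: int = 200

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("ROI side must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI corner must be non-negative")
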