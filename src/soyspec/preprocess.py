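"""Spectral preprocessing transforms.

Eight sample-wise transforms commonly used on visible/NIR reflectance spectra:

==== =========================================================
BC   baseline correction (endpoint-anchored linear baseline)
MA   centered moving average
SGD  Savitzky-Golay convolution derivative
NORM per-spectrum min-max normalization to [0, 1]
SNV  standard normal variate (per-spectrum standardization)
MSC  multiplicative scatter correction against a reference
DS   derivative spectroscopy (plain first finite difference)
SGS  Savitzky-Golay convolution smoothing
==== =========================================================

All transforms operate row by row; MSC alone carries shared state (its
reference spectrum), which :class:`PreprocessChain` fits on calibration data
only so no information leaks from held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectraTable, WavelengthGrid

METHODS = ("BC", "MA", "SGD", "NORM", "SNV", "MSC", "DS", "SGS", "NONE")


@dataclass(frozen=True)
class PreprocessSpec:
    """A named transform plus its parameters.

    window/polyorder/deriv_order apply to the windowed methods (MA, SGD, SGS;
    deriv_order also to DS); ``reference`` is MSC's reference spectrum (None =
    compute from the data it is fitted on); ``baseline`` selects the BC
    variant ("linear" endpoint-anchored line, or "offset" per-spectrum
    minimum subtraction).
    """

    method: str
    window: int = 11
    polyorder: int = 2
    deriv_order: int = 1
    reference: np.ndarray | None = None
    baseline: str = "linear"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method in ("MA", "SGD", "SGS"):
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("window must be an odd integer >= 3")
        if self.method in ("SGD", "SGS"):
            if self.polyorder < 1 or self.window <= self.polyorder:
                raise ValueError("window must exceed polyorder (>= 1)")
        if self.method in ("SGD", "DS") and self.deriv_order < 1:
            raise ValueError("deriv_order must be >= 1")
        if self.method == "SGD" and self.deriv_order > self.polyorder:
            raise ValueError("deriv_order must be <= polyorder for SGD")
        if self.baseline not in ("linear", "offset"):
            raise ValueError("baseline must be 'linear' or 'offset'")

    @property
    def changes_band_count(self) -> bool:
        return self.method == "DS"


def _baseline_correct(X: np.ndarray, mode: str) -> np.ndarray:
    if mode == "offset":
        return X - X.min(axis=1, keepdims=True)
    n = X.shape[1]
    t = np.linspace(0.0, 1.0, n)
    first, last = X[:, :1], X[:, -1:]
    return X - (first + (last - first) * t)


def _moving_average(X: np.ndarray, window: int) -> np.ndarray:
    # truncated window at the edges: out[i] = mean(x[max(0,i-h) : i+h+1])
    n = X.shape[1]
    if window > n:
        raise ValueError(f"MA window {window} exceeds band count {n}")
    kernel = np.ones(window)
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, X)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts


def _minmax(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=1, keepdims=True)
    rng = X.max(axis=1, keepdims=True) - lo
    flat = np.flatnonzero(rng.ravel() == 0)
    if flat.size:
        raise ValueError(f"cannot min-max normalize constant spectrum at row {flat[0]}")
    return (X - lo) / rng


def _snv(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"SNV undefined for constant spectrum at row {flat[0]}")
    return (X - mu) / sd


def _msc(X: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("MSC reference length must equal band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        b = (x - x.mean()) @ ref_c / denom
        if b == 0:
            raise ValueError(f"MSC slope b = 0 at row {i}")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return out


def _savgol(X: np.ndarray, spec: PreprocessSpec, delta: float, deriv: int) -> np.ndarray:
    if spec.window > X.shape[1]:
        raise ValueError(f"SG window {spec.window} exceeds band count {X.shape[1]}")
    return savgol_filter(X, spec.window, spec.polyorder, deriv=deriv,
                         delta=delta, axis=1, mode="interp")


def apply_preprocess(table: SpectraTable, spec: PreprocessSpec) -> SpectraTable:
    """Apply one transform to every spectrum of a table.

    Band count is preserved by all methods except DS, which returns
    ``n_bands - 1`` finite differences on the grid midpoints. Labels, sample
    ids and row order are always preserved.
    """
    X = table.reflectance
    m = spec.method
    if m == "NONE":
        return table
    if m == "BC":
        return table.with_reflectance(_baseline_correct(X, spec.baseline))
    if m == "MA":
        return table.with_reflectance(_moving_average(X, spec.window))
    if m == "NORM":
        return table.with_reflectance(_minmax(X))
    if m == "SNV":
        return table.with_reflectance(_snv(X))
    if m == "MSC":
        return table.with_reflectance(_msc(X, spec.reference))
    if m == "SGD":
        return table.with_reflectance(
            _savgol(X, spec, table.grid.spacing, spec.deriv_order))
    if m == "SGS":
        return table.with_reflectance(_savgol(X, spec, table.grid.spacing, 0))
    if m == "DS":
        dlam = np.diff(table.wavelengths)
        out = np.diff(X, axis=1) / dlam
        mid = WavelengthGrid((table.wavelengths[:-1] + table.wavelengths[1:]) / 2)
        for _ in range(spec.deriv_order - 1):
            dmid = np.diff(mid.centers)
            out = np.diff(out, axis=1) / dmid
            mid = WavelengthGrid((mid.centers[:-1] + mid.centers[1:]) / 2)
        return table.with_reflectance(out, mid)
    raise AssertionError(m)


class PreprocessChain:
    """An ordered composition of transforms with leak-free MSC fitting.

    ``fit(calibration)`` resolves every MSC step's reference on the
    calibration rows (propagated through the preceding steps) and freezes it;
    ``transform`` then applies the frozen chain to any table. Calling an
    unfitted chain fits it on its input (self-referential MSC), which is the
    correct behaviour outside a calibration/prediction protocol.
    """

    def __init__(self, specs):
        specs = list(specs)
        for i, s in enumerate(specs):
            if s.changes_band_count and i != len(specs) - 1:
                raise ValueError("DS changes the band count and must be the last step")
        self.specs = specs
        self._fitted: list[PreprocessSpec] | None = None

    def fit(self, table: SpectraTable) -> "PreprocessChain":
        fitted = []
        current = table
        for s in self.specs:
            if s.method == "MSC" and s.reference is None:
                s = replace(s, reference=current.reflectance.mean(axis=0))
            current = apply_preprocess(current, s)
            fitted.append(s)
        self._fitted = fitted
        return self

    def transform(self, table: SpectraTable) -> SpectraTable:
        specs = self._fitted if self._fitted is not None else self.specs
        for s in specs:
            table = apply_preprocess(table, s)
        return table

    def __call__(self, table: SpectraTable) -> SpectraTable:
        if self._fitted is None:
            self.fit(table)
        return self.transform(table)


def make_chain(specs) -> PreprocessChain:
    """Compose an ordered list of :class:`PreprocessSpec` into one transform.

    The empty list yields the identity transform.
    """
    return PreprocessChain(specs)
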