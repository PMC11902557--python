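"""Calibration/prediction partitioning by SPXY (joint x-y distance).

SPXY extends Kennard-Stone set selection with a response term: samples are
greedily picked to maximize the minimum joint distance

    d(i, j) = d_x(i, j) / max d_x  +  d_y(i, j) / max d_y

to the already-selected calibration set, where d_x is Euclidean distance
between spectra and d_y a distance on the labels. For a categorical response
d_y is the 0/1 discrete metric (same class -> 0, different -> 1), normalized
like d_x; with a single class the d_y term vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import SpectraTable


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index sets covering all rows.

    ``calibration_idx`` is in greedy selection order; ``prediction_idx`` is
    ascending.
    """

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = set(self.calibration_idx.tolist())
        pred = set(self.prediction_idx.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


def joint_distance_matrix(table: SpectraTable) -> np.ndarray:
    """The normalized joint x-y distance matrix used by SPXY."""
    dx = squareform(pdist(table.reflectance, metric="euclidean"))
    mx = dx.max()
    if mx == 0:
        raise ValueError("degenerate distance matrix: all spectra identical")
    d = dx / mx
    labels = np.asarray(table.labels)
    dy = (labels[:, None] != labels[None, :]).astype(float)
    if dy.max() > 0:
        d = d + dy / dy.max()
    return d


def spxy_split(table: SpectraTable, ratio: float = 0.8) -> SplitResult:
    """Deterministic SPXY split at calibration fraction ``ratio`` (default 4:1).

    The first two calibration members are the pair at maximum joint distance;
    each subsequent member maximizes its minimum distance to the selected set.
    Ties break toward the lowest sample index, making the result invariant
    to everything but genuine ties.
    """
    n = table.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    d = joint_distance_matrix(table)
    n_cal = max(2, int(np.floor(ratio * n + 0.5)))
    n_cal = min(n_cal, n - 1)

    # seed pair: maximum joint distance, lexicographic lowest on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = np.flatnonzero(flat == flat.max())[0]
    selected = [int(iu[0][best]), int(iu[1][best])]
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    min_d[selected] = -np.inf

    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d))  # argmax takes the lowest index on ties
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf

    cal = np.array(selected, dtype=int)
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, ratio)


def random_split(table: SpectraTable, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Seeded uniform split (testing fallback; SPXY is the primary method)."""
    n = table.n_samples
    n_cal = max(2, int(np.floor(ratio * n + 0.5)))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(perm[:n_cal], np.sort(perm[n_cal:]), ratio)
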