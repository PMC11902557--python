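"""Feature-wavelength selection: SPA and CARS.

SPA (successive projections algorithm) grows a chain of minimally collinear
bands: starting from a chosen band, each step adds the band whose
(mean-centered) column retains the largest norm after orthogonal projection
onto the complement of the span of the bands already chosen.

CARS (competitive adaptive reweighted sampling) shrinks the band pool over
Monte-Carlo iterations along an exponentially decreasing retained-count
schedule (EDF), reweighting bands by the importance scores of a classifier
refitted on a random row subsample each iteration.

Both selectors are driven by a classification-accuracy evaluator (by default
a random forest scored on the held-out prediction partition), and report the
accuracy trace that justified the chosen subset size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraTable


@dataclass
class SelectionResult:
    """An ordered selected-band subset with its supporting accuracy trace."""

    selected_idx: np.ndarray
    selected_nm: np.ndarray
    accuracy_trace: dict
    n_bands_total: int
    method: str = ""
    best_accuracy: float = float("nan")

    @property
    def fraction_of_total(self) -> float:
        """|selected| / n_bands — the 'percent of total wavelengths' statistic."""
        return len(self.selected_idx) / self.n_bands_total


@dataclass(frozen=True)
class CarsSchedule:
    """Retained band counts per CARS iteration (non-increasing, p -> 2)."""

    n_runs: int
    retained: np.ndarray = field(hash=False)


def edf_schedule(p: int, n_runs: int) -> CarsSchedule:
    """Exponentially decreasing retained-count schedule.

    retained[i] = round(p * a * exp(-k i)) for i = 1..N, with a and k fixed
    by the endpoints retained[1] = p and retained[N] = 2:
    a = (p/2)^(1/(N-1)), k = ln(p/2)/(N-1).
    """
    if p < 2 or n_runs < 2:
        raise ValueError("need p >= 2 and n_runs >= 2")
    i = np.arange(1, n_runs + 1)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    retained = np.clip(np.round(p * a * np.exp(-k * i)).astype(int), 2, p)
    return CarsSchedule(n_runs, retained)


def spa_chain(X: np.ndarray, start: int, k_max: int) -> np.ndarray:
    """Successive-projections chain of ``k_max`` band indices from ``start``.

    Columns are mean-centered internally; each step picks the candidate
    column with the largest norm after projecting out the span of the chain
    so far (ties to the lowest index).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k_max <= min(n - 1, p):
        raise ValueError(f"k_max must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    R = X - X.mean(axis=0)
    chain = [int(start)]
    norm0 = np.linalg.norm(R[:, start])
    tol = 1e-12 * max(1.0, float(np.abs(R).max()))
    for _ in range(k_max - 1):
        q = R[:, chain[-1]]
        nq = np.linalg.norm(q)
        if nq <= tol:
            raise ValueError("collinear exhaustion: zero-norm column in chain")
        q = q / nq
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))
        if norms[best] <= tol:
            raise ValueError("collinear exhaustion: all candidate columns in span")
        chain.append(best)
    if norm0 <= tol and k_max > 1:
        raise ValueError("collinear exhaustion: start column has zero norm")
    return np.array(chain, dtype=int)


def spa_select(cal: SpectraTable, pred: SpectraTable, evaluator,
               k_range, starts=None) -> SelectionResult:
    """SPA subset selection scored by classification accuracy.

    For each subset size ``k`` in ``k_range`` and each start band, builds the
    projection chain and scores its first ``k`` members with ``evaluator``
    (band-index array -> accuracy on the prediction partition). Returns the
    accuracy-maximizing subset; ties prefer the smaller ``k``, then the start
    band at the lower wavelength. ``starts=None`` tries every band.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    p = cal.n_bands
    k_cap = min(cal.n_samples - 1, p)
    if k_range[-1] > k_cap:
        raise ValueError(f"k_range exceeds max chain length {k_cap}")
    if starts is None:
        starts = range(p)
    starts = [int(s) for s in starts]

    best = None  # (acc, k, start_wavelength, subset)
    trace: dict[int, float] = {}
    k_max = k_range[-1]
    for s in starts:
        try:
            chain = spa_chain(cal.reflectance, s, k_max)
        except ValueError:
            continue  # degenerate start (e.g. constant band)
        for k in k_range:
            subset = chain[:k]
            acc = float(evaluator(subset))
            trace[k] = max(trace.get(k, -np.inf), acc)
            key = (-acc, k, cal.wavelengths[s])
            if best is None or key < best[0]:
                best = (key, subset)
    if best is None:
        raise ValueError("collinear exhaustion: no valid SPA chain from any start")
    subset = best[1]
    return SelectionResult(subset, cal.wavelengths[subset], trace, p,
                           method="SPA", best_accuracy=-best[0][0])


def cars_select(cal: SpectraTable, pred: SpectraTable, evaluator, *,
                n_runs: int = 50, seed: int = 0, importance=None,
                sample_frac: float = 0.8) -> SelectionResult:
    """CARS subset selection scored by classification accuracy.

    Each Monte-Carlo iteration refits the importance model on a random
    ``sample_frac`` row subsample of the calibration set, normalizes the
    band weights, enforces the EDF retained count by keeping the
    top-weighted bands, and draws the working subset by adaptive reweighted
    sampling (importance-weighted draw without replacement). Every
    iteration's subset is scored with ``evaluator``; the best-scoring subset
    wins (ties prefer the smaller subset, then the earlier iteration).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    p = cal.n_bands
    schedule = edf_schedule(p, n_runs)
    if importance is None:
        importance = _default_rf_importance(cal, seed)

    pool = np.arange(p)
    n_rows = cal.n_samples
    n_sub = max(2, int(round(sample_frac * n_rows)))
    best = None  # (acc, size, iteration, subset)
    trace: dict[int, float] = {}
    for it, r in enumerate(schedule.retained, start=1):
        if r > pool.size:
            raise RuntimeError("schedule violation: retained count exceeds pool")
        rows = rng.choice(n_rows, size=n_sub, replace=False)
        w = np.asarray(importance(rows, pool), dtype=float)
        w = np.clip(w, 0.0, None)
        w = w / w.sum() if w.sum() > 0 else np.full(pool.size, 1.0 / pool.size)
        # enforced EDF shrink: keep the top-weighted r bands of the pool
        top = np.sort(np.argsort(-w, kind="stable")[:r])
        kept, kept_w = pool[top], w[top]
        # adaptive reweighted sampling within the kept set (weighted draw
        # without replacement; fixes the subset order, membership = kept set)
        kept_w = kept_w + 1e-12  # floor lets zero-importance bands be drawn last-ish
        kept_w = kept_w / kept_w.sum()
        order = rng.choice(r, size=r, replace=False, p=kept_w)
        subset = kept[order]
        acc = float(evaluator(subset))
        key = (-acc, subset.size, it)
        if best is None or key < best[0]:
            best = (key, np.sort(subset))
        prev = trace.get(subset.size, -np.inf)
        trace[subset.size] = max(prev, acc)
        pool = np.sort(kept)
    subset = best[1]
    return SelectionResult(subset, cal.wavelengths[subset], trace, p,
                           method="CARS", best_accuracy=-best[0][0])


def _default_rf_importance(cal: SpectraTable, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    def importance(rows: np.ndarray, bands: np.ndarray) -> np.ndarray:
        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        rf.fit(cal.reflectance[np.ix_(rows, bands)], cal.labels[rows])
        return rf.feature_importances_

    return importance
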