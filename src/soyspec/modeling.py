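"""Classifiers and hyperparameter optimization.

The primary classifier is a random forest (bagged CART ensemble) whose
impurity-based feature importances serve as band "contribution rates";
k-nearest-neighbors and an RBF-kernel SVM are comparators. RF hyperparameters
can be tuned with canonical global-best particle swarm optimization (PSO) or
DE/rand/1/bin differential evolution against a stratified cross-validation
accuracy fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import SpectraTable

MODEL_KINDS = ("RF", "KNN", "SVM")

#: Default (untuned) RF hyperparameters.
DEFAULT_RF_PARAMS = {
    "n_trees": 100,
    "max_depth": 30,          # effectively unlimited at these sample sizes
    "min_samples_split": 2,
    "max_features_fraction": 1.0,
}


@dataclass(frozen=True)
class HyperparamSpace:
    """Box bounds per hyperparameter; integer dims are rounded at evaluation.

    Bounds are stored as name -> (low, high, is_integer).
    """

    bounds: dict = field(default_factory=lambda: {
        "n_trees": (10, 500, True),
        "max_depth": (2, 30, True),
        "min_samples_split": (2, 10, True),
        "max_features_fraction": (0.1, 1.0, False),
    })

    def __post_init__(self) -> None:
        for name, (lo, hi, _) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: [{lo}, {hi}]")

    @property
    def names(self) -> list:
        return list(self.bounds)

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()], dtype=float)

    @property
    def highs(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()], dtype=float)

    def decode(self, x: np.ndarray) -> dict:
        """Clip a continuous vector into bounds and round integer dims."""
        out = {}
        for xi, (name, (lo, hi, is_int)) in zip(x, self.bounds.items()):
            v = min(max(float(xi), lo), hi)
            out[name] = int(round(v)) if is_int else v
        return out

    def encode(self, params: dict) -> np.ndarray:
        return np.array([float(params[name]) for name in self.bounds], dtype=float)


@dataclass
class TunedModel:
    """A fitted classifier plus its resolved hyperparameters and diagnostics."""

    kind: str
    hyperparams: dict
    estimator: object
    train_accuracy: float
    band_importance: np.ndarray | None
    classes: np.ndarray
    n_bands: int


def _build_estimator(kind: str, hp: dict, seed: int):
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 100)),
            max_depth=int(hp["max_depth"]) if hp.get("max_depth") else None,
            min_samples_split=int(hp.get("min_samples_split", 2)),
            max_features=float(hp.get("max_features_fraction", 1.0)),
            random_state=seed,
        )
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=int(hp.get("n_neighbors", 5)))
    if kind == "SVM":
        return SVC(kernel="rbf", C=float(hp.get("C", 1.0)),
                   gamma=hp.get("gamma", "scale"), random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def train_classifier(cal: SpectraTable, kind: str = "RF",
                     hyperparams: dict | None = None, seed: int = 0) -> TunedModel:
    """Fit a classifier on the calibration table.

    RF exposes normalized impurity-based band importances (summing to 1);
    KNN and SVM report ``band_importance = None``.
    """
    hp = dict(hyperparams or {})
    if kind == "RF":
        hp = {**DEFAULT_RF_PARAMS, **hp}
    if np.unique(cal.labels).size < 2:
        raise ValueError("calibration set holds a single class; cannot train")
    est = _build_estimator(kind, hp, seed)
    est.fit(cal.reflectance, cal.labels)
    train_acc = float(np.mean(est.predict(cal.reflectance) == cal.labels))
    importance = None
    if kind == "RF":
        imp = np.asarray(est.feature_importances_, dtype=float)
        s = imp.sum()
        importance = imp / s if s > 0 else np.full_like(imp, 1.0 / imp.size)
    return TunedModel(kind, hp, est, train_acc, importance,
                      np.unique(cal.labels), cal.n_bands)


def predict(model: TunedModel, table: SpectraTable) -> np.ndarray:
    """Predict one label per row; the table must match the training bands."""
    if table.n_bands != model.n_bands:
        raise ValueError(
            f"band-count mismatch: model expects {model.n_bands}, got {table.n_bands}"
        )
    return np.asarray(model.estimator.predict(table.reflectance))


def make_rf_evaluator(cal: SpectraTable, pred: SpectraTable,
                      hyperparams: dict | None = None, seed: int = 0):
    """Band-subset -> prediction-set accuracy callback (RF), for the selectors."""

    def evaluator(bands) -> float:
        bands = np.sort(np.asarray(bands, dtype=int))  # grids must stay increasing
        model = train_classifier(cal.take_bands(bands), "RF", hyperparams, seed)
        yhat = predict(model, pred.take_bands(bands))
        return float(np.mean(yhat == pred.labels))

    return evaluator


def cv_fitness(cal: SpectraTable, hyperparams: dict, folds: int = 5,
               seed: int = 0) -> float:
    """Stratified k-fold mean accuracy of an RF with the given hyperparameters."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(cal.labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {counts.min()} members; use folds <= {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(cal.reflectance, cal.labels):
        model = train_classifier(cal.take_rows(tr), "RF", hyperparams, seed)
        yhat = predict(model, cal.take_rows(te))
        accs.append(np.mean(yhat == cal.labels[te]))
    return float(np.mean(accs))


@dataclass(frozen=True)
class OptimizerConfig:
    """Shared PSO/DE settings (fields irrelevant to one algorithm are ignored)."""

    population: int = 20
    iterations: int = 30
    seed: int = 0
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    mutation: float = 0.7     # DE differential weight F
    crossover: float = 0.9    # DE crossover rate CR

    def __post_init__(self) -> None:
        if self.population < 1 or self.iterations < 1:
            raise ValueError("population and iterations must be >= 1")


def _init_population(space: HyperparamSpace, n: int, rng, x0) -> np.ndarray:
    lo, hi = space.lows, space.highs
    pop = lo + rng.random((n, lo.size)) * (hi - lo)
    if x0 is not None:
        pop[0] = np.clip(space.encode(x0) if isinstance(x0, dict) else np.asarray(x0, float), lo, hi)
    return pop


def pso_optimize(space: HyperparamSpace, fitness, config: OptimizerConfig,
                 x0: dict | None = None):
    """Global-best PSO maximizing ``fitness(params dict)``.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);
    positions clipped to bounds; integer dims rounded at evaluation only.
    ``x0`` (e.g. the default hyperparameters) seeds one initial particle, so
    the tuned result can never score below the default on the same fitness.
    Returns (best params dict, best fitness, per-iteration gbest history).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = space.lows, space.highs
    x = _init_population(space, config.population, rng, x0)
    v = (rng.random(x.shape) - 0.5) * (hi - lo) * 0.1
    pbest = x.copy()
    pfit = np.array([fitness(space.decode(xi)) for xi in x], dtype=float)
    g = int(np.argmax(pfit))
    gbest, gfit = pbest[g].copy(), float(pfit[g])
    history = [gfit]
    for _ in range(config.iterations):
        r1 = rng.random(x.shape)
        r2 = rng.random(x.shape)
        v = (config.inertia * v
             + config.cognitive * r1 * (pbest - x)
             + config.social * r2 * (gbest - x))
        x = np.clip(x + v, lo, hi)
        fit = np.array([fitness(space.decode(xi)) for xi in x], dtype=float)
        improved = fit > pfit
        pbest[improved] = x[improved]
        pfit[improved] = fit[improved]
        g = int(np.argmax(pfit))
        if pfit[g] > gfit:
            gbest, gfit = pbest[g].copy(), float(pfit[g])
        history.append(gfit)
    return space.decode(gbest), gfit, np.array(history)


def de_optimize(space: HyperparamSpace, fitness, config: OptimizerConfig,
                x0: dict | None = None):
    """DE/rand/1/bin maximizing ``fitness(params dict)``.

    Mutant = a + F (b - c) over distinct random members; binomial crossover
    at rate CR with one forced dimension; greedy replacement; bounds by
    clipping; integer dims rounded at evaluation. ``x0`` seeds one initial
    member. Returns (best params dict, best fitness, gbest history).
    """
    if config.population < 4:
        raise ValueError("DE needs a population of at least 4")
    rng = np.random.default_rng(config.seed)
    lo, hi = space.lows, space.highs
    n, d = config.population, lo.size
    x = _init_population(space, n, rng, x0)
    fit = np.array([fitness(space.decode(xi)) for xi in x], dtype=float)
    history = [float(fit.max())]
    for _ in range(config.iterations):
        for i in range(n):
            a, b, c = rng.choice([j for j in range(n) if j != i], size=3, replace=False)
            mutant = np.clip(x[a] + config.mutation * (x[b] - x[c]), lo, hi)
            cross = rng.random(d) < config.crossover
            cross[rng.integers(d)] = True
            trial = np.where(cross, mutant, x[i])
            tfit = fitness(space.decode(trial))
            if tfit >= fit[i]:
                x[i], fit[i] = trial, tfit
        history.append(float(fit.max()))
    best = int(np.argmax(fit))
    return space.decode(x[best]), float(fit[best]), np.array(history)


def tune_rf(cal: SpectraTable, algorithm: str = "DE",
            space: HyperparamSpace | None = None,
            config: OptimizerConfig | None = None,
            folds: int = 5, seed: int | None = None):
    """Tune RF hyperparameters against stratified-CV accuracy.

    Returns (best hyperparams, best CV accuracy, history). The default
    hyperparameters are seeded into the initial population, so the tuned CV
    accuracy is never below the default's.
    """
    space = space or HyperparamSpace()
    config = config or OptimizerConfig()
    if seed is not None:
        config = OptimizerConfig(**{**config.__dict__, "seed": seed})

    cache: dict = {}

    def fitness(params: dict) -> float:
        key = tuple(sorted(params.items()))
        if key not in cache:
            cache[key] = cv_fitness(cal, params, folds=folds, seed=config.seed)
        return cache[key]

    opt = {"PSO": pso_optimize, "DE": de_optimize}.get(algorithm.upper())
    if opt is None:
        raise ValueError(f"unknown optimizer {algorithm!r}; expected PSO or DE")
    return opt(space, fitness, config, x0=DEFAULT_RF_PARAMS)
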