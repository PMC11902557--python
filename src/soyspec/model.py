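"""High-level Model/Results interface for soybean-component classification.

:class:`SoybeanComponentModel` is constructed from a spectra table (or
DataFrame/CSV) together with the analysis choices — band exclusions, a
preprocessing chain, the SPXY split ratio, an optional feature-wavelength
selector and an optional hyperparameter optimizer. ``fit()`` executes
trim -> split -> preprocess -> select -> tune -> train -> evaluate and
returns a :class:`SoybeanComponentResults` with the held-out classification
report, band importances, selection trace and a printable ``summary()``.

Example
-------
>>> from soyspec import SoybeanComponentModel
>>> from soyspec.synthetic import default_config, generate_dataset
>>> table, _ = generate_dataset(default_config(seed=0))
>>> res = SoybeanComponentModel(table, seed=0).fit()
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectraTable
from .io import DEFAULT_EXCLUDED_RANGES, read_spectra_csv, trim_bands
from .metrics import ClassificationReport, ImportanceReport, classification_report
from .modeling import (OptimizerConfig, TunedModel, make_rf_evaluator, predict,
                       train_classifier, tune_rf)
from .preprocess import PreprocessSpec, make_chain
from .sampling import SplitResult, spxy_split
from .selection import SelectionResult, cars_select, spa_select


class SoybeanComponentModel:
    """Spectral classification model for intact grain / broken grain / impurity.

    Parameters
    ----------
    table:
        Labeled reflectance spectra (rows = samples).
    preprocess:
        Ordered method names or :class:`PreprocessSpec` objects; fitted on
        calibration rows only.
    exclude:
        Closed wavelength intervals (nm) trimmed before everything else.
    split_ratio:
        SPXY calibration fraction (0.8 = the conventional 4:1 split).
    selector:
        None, "SPA" or "CARS" for feature-wavelength selection.
    optimizer:
        None, "PSO" or "DE" for RF hyperparameter tuning.
    kind:
        "RF" (primary), "KNN" or "SVM".
    """

    def __init__(self, table: SpectraTable, *, preprocess=(), exclude=DEFAULT_EXCLUDED_RANGES,
                 split_ratio: float = 0.8, selector: str | None = None,
                 spa_k_range=range(1, 13), spa_starts=None, cars_runs: int = 50,
                 optimizer: str | None = None, optimizer_config: OptimizerConfig | None = None,
                 cv_folds: int = 5, kind: str = "RF", seed: int = 0):
        self.table = table
        self.preprocess = [p if isinstance(p, PreprocessSpec) else PreprocessSpec(p)
                           for p in preprocess]
        self.exclude = exclude
        self.split_ratio = split_ratio
        self.selector = selector
        self.spa_k_range = spa_k_range
        self.spa_starts = spa_starts
        self.cars_runs = cars_runs
        self.optimizer = optimizer
        self.optimizer_config = optimizer_config
        self.cv_folds = cv_folds
        self.kind = kind
        self.seed = seed

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SoybeanComponentModel":
        return cls(read_spectra_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       **kwargs) -> "SoybeanComponentModel":
        return cls(SpectraTable.from_dataframe(df, label_column), **kwargs)

    def fit(self) -> "SoybeanComponentResults":
        table = trim_bands(self.table, self.exclude) if self.exclude else self.table
        split = spxy_split(table, self.split_ratio)
        cal_raw = table.take_rows(split.calibration_idx)
        pred_raw = table.take_rows(split.prediction_idx)
        chain = make_chain(self.preprocess).fit(cal_raw)
        cal, pred = chain.transform(cal_raw), chain.transform(pred_raw)

        sel: SelectionResult | None = None
        if self.selector is not None:
            evaluator = make_rf_evaluator(cal, pred, seed=self.seed)
            if self.selector.upper() == "SPA":
                starts = self.spa_starts
                if isinstance(starts, int):
                    starts = np.unique(np.linspace(0, cal.n_bands - 1, starts).astype(int))
                sel = spa_select(cal, pred, evaluator, self.spa_k_range, starts=starts)
            elif self.selector.upper() == "CARS":
                sel = cars_select(cal, pred, evaluator, n_runs=self.cars_runs,
                                  seed=self.seed)
            else:
                raise ValueError(f"unknown selector {self.selector!r}")
            bands = np.sort(np.asarray(sel.selected_idx))
            cal, pred = cal.take_bands(bands), pred.take_bands(bands)

        tuning_history = None
        hyperparams = None
        if self.optimizer is not None:
            if self.kind != "RF":
                raise ValueError("hyperparameter tuning is wired for RF only")
            cfg = self.optimizer_config or OptimizerConfig(seed=self.seed)
            hyperparams, _, tuning_history = tune_rf(
                cal, self.optimizer, config=cfg, folds=self.cv_folds)

        model = train_classifier(cal, self.kind, hyperparams, seed=self.seed)
        yhat = predict(model, pred)
        report = classification_report(pred.labels, yhat, classes=model.classes)
        return SoybeanComponentResults(self, chain, split, sel, model, cal, pred,
                                       report, tuning_history)


@dataclass
class SoybeanComponentResults:
    """Fit artifacts: held-out report, importances, selection and tuning traces."""

    model_spec: SoybeanComponentModel
    chain: object
    split: SplitResult
    selection: SelectionResult | None
    model: TunedModel
    calibration: SpectraTable
    prediction: SpectraTable
    report: ClassificationReport
    tuning_history: np.ndarray | None

    @property
    def overall_accuracy(self) -> float:
        return self.report.overall_accuracy

    @property
    def importance(self) -> ImportanceReport | None:
        if self.model.band_importance is None:
            return None
        return ImportanceReport(self.model.band_importance,
                                self.calibration.wavelengths)

    def predict(self, table: SpectraTable) -> np.ndarray:
        """Classify new spectra (full-grid input: trimmed, preprocessed and
        band-subset exactly as during the fit)."""
        spec = self.model_spec
        if spec.exclude:
            table = trim_bands(table, spec.exclude)
        table = self.chain.transform(table)
        if self.selection is not None:
            table = table.take_bands(np.sort(np.asarray(self.selection.selected_idx)))
        return predict(self.model, table)

    def summary(self, decimals: int = 4) -> str:
        """Printable fit summary in the field's report-table layout."""
        spec = self.model_spec
        lines = [
            "Soybean component classification",
            "=" * 58,
            f"model:            {self.model.kind}",
            f"preprocessing:    {'-'.join(s.method for s in spec.preprocess) or 'none'}",
            f"selector:         {spec.selector or 'none (all bands)'}",
            f"optimizer:        {spec.optimizer or 'none (default hyperparams)'}",
            f"bands used:       {self.calibration.n_bands}",
            f"calibration rows: {self.calibration.n_samples}",
            f"prediction rows:  {self.prediction.n_samples}",
        ]
        if self.selection is not None:
            pct = 100.0 * self.selection.fraction_of_total
            nm = ", ".join(f"{w:.2f}" for w in self.selection.selected_nm)
            lines += [f"selected bands:   {nm}",
                      f"fraction of grid: {pct:.2f}%"]
        if self.model.kind == "RF":
            lines.append(f"hyperparameters:  {self.model.hyperparams}")
        lines.append("-" * 58)
        lines.append(f"{'class':<12}{'precision':>10}{'recall':>10}{'F1':>10}{'support':>9}")
        r = self.report
        for i, c in enumerate(r.classes):
            lines.append(f"{str(c):<12}{r.precision[i]:>10.{decimals}f}"
                         f"{r.recall[i]:>10.{decimals}f}{r.f1[i]:>10.{decimals}f}"
                         f"{r.support[i]:>9d}")
        lines.append("-" * 58)
        lines.append(f"overall accuracy: {r.overall_accuracy:.{decimals}f}")
        imp = self.importance
        if imp is not None:
            k = min(3, len(imp.importances))
            top = imp.top_k(k)
            bands = ", ".join(f"{w:.2f} nm ({v:.4f})" for w, v in
                              zip(top.wavelength_nm, top.importance))
            lines.append(f"top-{k} bands:      {bands}")
            lines.append(f"top-{k} cumulative contribution: {imp.cumulative(k):.4f}")
        return "\n".join(lines)

    def plot_importance(self, ax=None, top: int | None = None):
        """Bar plot of band importances over wavelength (RF only)."""
        imp = self.importance
        if imp is None:
            raise ValueError(f"{self.model.kind} exposes no band importances")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        order = imp.ranking[:top] if top else np.arange(len(imp.importances))
        ax.bar(imp.wavelengths[order], imp.importances[order],
               width=max(1.0, self.calibration.grid.spacing * 0.8))
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("importance")
        ax.set_title("RF band contribution rates")
        return ax
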