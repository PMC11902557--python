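"""Declarative experiment pipeline: trim -> split -> preprocess -> select ->
tune -> train -> evaluate, over a grid of preprocessing chains, selectors,
optimizers and model kinds.

One :class:`PipelineConfig` reproduces a whole study shape; every grid cell
emits its selection result, tuned hyperparameters, classification report and
band importances, plus a run manifest carrying the seed, package versions
and a configuration hash so identical configs give byte-identical numbers.

The split is computed on the trimmed raw spectra, then every preprocessing
chain is fitted on the calibration rows only (MSC references and any other
fitted state never see prediction rows) and applied to both partitions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .containers import SpectraTable
from .io import DEFAULT_EXCLUDED_RANGES, read_spectra_csv, trim_bands
from .metrics import ImportanceReport, classification_report
from .modeling import (OptimizerConfig, make_rf_evaluator, predict,
                       train_classifier, tune_rf)
from .preprocess import PreprocessSpec, make_chain
from .sampling import spxy_split
from .selection import cars_select, spa_select
from .synthetic import default_config, generate_dataset

log = logging.getLogger("soyspec.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from a JSON dict."""

    input_csv: str | None = None            # None -> synthetic default dataset
    exclude: tuple = DEFAULT_EXCLUDED_RANGES
    chains: tuple = (("NONE",),)            # each chain = tuple of method names
    split_ratio: float = 0.8
    selectors: tuple = (None,)              # None | "SPA" | "CARS"
    optimizers: tuple = (None,)             # None | "PSO" | "DE"
    model_kinds: tuple = ("RF",)
    spa_k_range: tuple = (1, 12)
    spa_starts: int | None = None           # cap on SPA start bands (None = all)
    cars_runs: int = 50
    optimizer_config: dict = field(default_factory=dict)
    cv_folds: int = 5
    outdir: str = "soyspec_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["exclude"] = [list(iv) for iv in self.exclude]
        d["chains"] = [list(c) for c in self.chains]
        for k in ("selectors", "optimizers", "model_kinds", "spa_k_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "exclude" in d:
            d["exclude"] = tuple(tuple(iv) for iv in d["exclude"])
        if "chains" in d:
            d["chains"] = tuple(tuple(c) for c in d["chains"])
        for k in ("selectors", "optimizers", "model_kinds", "spa_k_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_input(config: PipelineConfig) -> SpectraTable:
    if config.input_csv is not None:
        return read_spectra_csv(config.input_csv)
    table, _ = generate_dataset(default_config(config.seed))
    return table


def _cell_name(chain, selector, optimizer, kind) -> str:
    return "_".join(["-".join(chain) or "NONE", selector or "ALL",
                     optimizer or "DEFAULT", kind])


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full experiment grid; returns the run directory.

    A failing grid cell is logged and recorded in the manifest; remaining
    cells still run.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_input(config)
    table = trim_bands(table, config.exclude)
    split = spxy_split(table, config.split_ratio)
    cal_raw, pred_raw = table.take_rows(split.calibration_idx), \
        table.take_rows(split.prediction_idx)

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "soyspec_version": __version__,
        "n_samples": table.n_samples,
        "n_bands": table.n_bands,
        "n_calibration": len(split.calibration_idx),
        "n_prediction": len(split.prediction_idx),
        "cells": {},
        "errors": {},
    }

    for chain_names in config.chains:
        chain = make_chain([PreprocessSpec(m) for m in chain_names])
        chain.fit(cal_raw)
        cal, pred = chain.transform(cal_raw), chain.transform(pred_raw)
        for selector in config.selectors:
            sel_result = None
            try:
                sel_result = _run_selector(cal, pred, selector, config)
            except Exception as exc:  # noqa: BLE001 - cell isolation
                log.exception("selection failed for %s/%s", chain_names, selector)
                manifest["errors"]["_".join(filter(None, (*chain_names, selector)))] = str(exc)
                continue
            if sel_result is not None:
                bands = np.sort(np.asarray(sel_result.selected_idx))
                cal_s, pred_s = cal.take_bands(bands), pred.take_bands(bands)
            else:
                cal_s, pred_s = cal, pred
            for optimizer in config.optimizers:
                for kind in config.model_kinds:
                    name = _cell_name(chain_names, selector, optimizer, kind)
                    t_cell = time.time()
                    try:
                        cell = _run_cell(cal_s, pred_s, sel_result, optimizer,
                                         kind, config, outdir / name)
                        cell["wall_s"] = round(time.time() - t_cell, 3)
                        manifest["cells"][name] = cell
                        log.info("cell %s: accuracy %.4f (%.1fs)", name,
                                 cell["overall_accuracy"], cell["wall_s"])
                    except Exception as exc:  # noqa: BLE001
                        log.exception("cell %s failed", name)
                        manifest["errors"][name] = str(exc)

    manifest["wall_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _run_selector(cal, pred, selector, config: PipelineConfig):
    if selector is None:
        return None
    evaluator = make_rf_evaluator(cal, pred, seed=config.seed)
    if selector.upper() == "SPA":
        k_lo, k_hi = config.spa_k_range
        starts = None
        if config.spa_starts is not None:
            # evenly spaced start bands keep large grids tractable
            starts = np.unique(np.linspace(0, cal.n_bands - 1,
                                           config.spa_starts).astype(int))
        return spa_select(cal, pred, evaluator, range(k_lo, k_hi + 1), starts=starts)
    if selector.upper() == "CARS":
        return cars_select(cal, pred, evaluator, n_runs=config.cars_runs,
                           seed=config.seed)
    raise ValueError(f"unknown selector {selector!r}")


def _run_cell(cal, pred, sel_result, optimizer, kind, config: PipelineConfig,
              cell_dir: Path) -> dict:
    cell_dir.mkdir(parents=True, exist_ok=True)
    hyperparams, history = None, None
    if optimizer is not None and kind == "RF":
        opt_cfg = OptimizerConfig(**{"seed": config.seed, **config.optimizer_config})
        hyperparams, best_cv, history = tune_rf(
            cal, optimizer, config=opt_cfg, folds=config.cv_folds)
    model = train_classifier(cal, kind, hyperparams, seed=config.seed)
    yhat = predict(model, pred)
    report = classification_report(pred.labels, yhat, classes=model.classes)

    cell = {
        "model_kind": kind,
        "hyperparams": model.hyperparams,
        "overall_accuracy": report.overall_accuracy,
        "n_bands": cal.n_bands,
    }
    report.to_dataframe().to_csv(cell_dir / "report.csv", index=False)
    (cell_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if sel_result is not None:
        (cell_dir / "selection.json").write_text(json.dumps({
            "method": sel_result.method,
            "selected_idx": sel_result.selected_idx.tolist(),
            "selected_nm": np.round(sel_result.selected_nm, 2).tolist(),
            "fraction_of_total": sel_result.fraction_of_total,
            "accuracy_trace": {str(k): v for k, v in
                               sorted(sel_result.accuracy_trace.items())},
        }, indent=2))
        cell["n_selected"] = int(len(sel_result.selected_idx))
        cell["fraction_of_total"] = sel_result.fraction_of_total
    if model.band_importance is not None:
        imp = ImportanceReport(model.band_importance, cal.wavelengths)
        imp.top_k(min(10, cal.n_bands)).to_csv(cell_dir / "importance.csv",
                                               index=False)
        cell["top3_cumulative_contribution"] = imp.cumulative(min(3, cal.n_bands))
    if history is not None:
        (cell_dir / "tuning.json").write_text(json.dumps({
            "optimizer": optimizer,
            "best_cv_accuracy": float(history.max()),
            "history": [float(h) for h in history],
            "hyperparams": model.hyperparams,
        }, indent=2))
    return cell
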