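"""Scoring of trained surrogates against the mechanistic simulator.

Per-output R² and MAE are computed in physical units (mmHg, mmol/L, pH
units) on a held-out test split, with a PASS/FAIL stamp against the
R² > 0.90 fidelity criterion for all four outputs, plus learning-curve
export and a simple slope-sign overfitting detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import INPUT_COLUMNS, OUTPUT_COLUMNS, is_labelled, SchemaError
from .trainer import SurrogateConfig, TrialRecord

__all__ = ["EvaluationReport", "r2_scores", "mae_scores", "overfit_flag",
           "learning_curves_export", "final_report", "R2_THRESHOLD"]

R2_THRESHOLD = 0.90


@dataclass
class EvaluationReport:
    """Per-output fidelity of one trained surrogate on a test split."""

    r2: dict[str, float]
    mae: dict[str, float]
    n_test: int
    config: SurrogateConfig | None = None
    overfit: bool = False
    passed: bool = field(init=False)
    failing_outputs: list[str] = field(init=False)

    def __post_init__(self):
        self.failing_outputs = [k for k, v in self.r2.items()
                                if v <= R2_THRESHOLD]
        self.passed = not self.failing_outputs

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "n_test": self.n_test,
                "overfit": self.overfit, "passed": self.passed,
                "failing_outputs": self.failing_outputs,
                "config": None if self.config is None else self.config.to_dict()}


def _as_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (rows x outputs)")
    return arr


def r2_scores(predicted, truth,
              names: Sequence[str] = OUTPUT_COLUMNS) -> dict[str, float]:
    """Coefficient of determination ``1 - SS_res / SS_tot`` per output."""
    P = _as_array(predicted, "predicted")
    T = _as_array(truth, "truth")
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {T.shape}")
    if len(T) < 2:
        raise ValueError("need at least 2 rows")
    ss_tot = np.sum((T - T.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        j = int(np.nonzero(ss_tot == 0)[0][0])
        raise ValueError(f"R^2 undefined: truth column {names[j]!r} is constant")
    ss_res = np.sum((T - P) ** 2, axis=0)
    vals = 1.0 - ss_res / ss_tot
    return {str(n): float(v) for n, v in zip(names, vals)}


def mae_scores(predicted, truth,
               names: Sequence[str] = OUTPUT_COLUMNS) -> dict[str, float]:
    """Mean absolute error per output, in physical units."""
    P = _as_array(predicted, "predicted")
    T = _as_array(truth, "truth")
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {T.shape}")
    return {str(n): float(v)
            for n, v in zip(names, np.mean(np.abs(P - T), axis=0))}


def overfit_flag(train_mae: Sequence[float], val_mae: Sequence[float]) -> bool:
    """True when, over the final third of training, validation MAE trends up
    while training MAE trends down (least-squares slope signs)."""
    train_mae = np.asarray(train_mae, dtype=float)
    val_mae = np.asarray(val_mae, dtype=float)
    n = len(train_mae)
    if n < 3 or n != len(val_mae):
        return False
    tail = slice(n - max(2, n // 3), n)
    x = np.arange(n)[tail]
    s_train = np.polyfit(x, train_mae[tail], 1)[0]
    s_val = np.polyfit(x, val_mae[tail], 1)[0]
    return bool(s_val > 0 and s_train < 0)


def learning_curves_export(records: Mapping[str, TrialRecord] | Sequence[TrialRecord],
                           out_dir, plot: bool = True) -> dict[str, bool]:
    """Write per-trial curve CSVs (epoch, train_mae, val_mae) and figures.

    Returns the overfitting flag per trial.  Empty histories are skipped
    with a warning.
    """
    if not isinstance(records, Mapping):
        records = {f"trial_{i}": r for i, r in enumerate(records)}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flags: dict[str, bool] = {}
    for name, rec in records.items():
        if not rec.train_mae:
            import logging
            logging.getLogger(__name__).warning(
                "trial %s has an empty history; skipped", name)
            continue
        df = pd.DataFrame({"epoch": np.arange(1, rec.epochs_consumed + 1),
                           "train_mae": rec.train_mae,
                           "val_mae": rec.val_mae})
        df.to_csv(out_dir / f"{name}_curve.csv", index=False)
        flags[name] = overfit_flag(rec.train_mae, rec.val_mae)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(df["epoch"], df["train_mae"], color="tab:blue",
                    label="training")
            ax.plot(df["epoch"], df["val_mae"], color="tab:orange",
                    label="validation")
            ax.set_xlabel("epoch")
            ax.set_ylabel("MAE (standardized)")
            ax.set_title(name)
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(out_dir / f"{name}_curve.png", dpi=110)
            plt.close(fig)
    return flags


def _row_hashes(table: pd.DataFrame) -> set:
    cols = table[list(INPUT_COLUMNS)].round(9)
    return set(pd.util.hash_pandas_object(cols, index=False).tolist())


def final_report(models: Mapping[str, tuple], test: pd.DataFrame,
                 train: pd.DataFrame | None = None,
                 out_dir=None) -> dict[str, EvaluationReport]:
    """Evaluate trained surrogates on a shared held-out labelled test split.

    ``models`` maps a name (e.g. the scheduler that selected the
    configuration) to a ``(trial, record)`` pair where ``trial`` exposes
    ``predict(table) -> (n, 4)`` and ``record`` is its training history.
    If ``train`` is given, test rows are hash-checked against it and any
    overlap raises (leakage guard).
    """
    if not is_labelled(test):
        raise SchemaError("test table must be labelled with the 4 outputs")
    if train is not None and _row_hashes(test) & _row_hashes(train):
        raise ValueError("data leakage: test rows overlap the training split")
    truth = test[list(OUTPUT_COLUMNS)].to_numpy(float)
    reports: dict[str, EvaluationReport] = {}
    for name, (trial, record) in models.items():
        pred = trial.predict(test)
        reports[name] = EvaluationReport(
            r2=r2_scores(pred, truth), mae=mae_scores(pred, truth),
            n_test=len(test),
            config=record.config if record is not None else None,
            overfit=overfit_flag(record.train_mae, record.val_mae)
            if record is not None else False)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump({k: r.to_dict() for k, r in reports.items()}, fh,
                      indent=2)
        _plot_r2_bars(reports, out_dir / "r2_scores.png")
    return reports


def _plot_r2_bars(reports: Mapping[str, EvaluationReport], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    n = len(reports)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, (name, rep) in zip(axes[0], reports.items()):
        keys = list(rep.r2)
        vals = [rep.r2[k] for k in keys]
        ax.bar(keys, vals, color="tab:blue")
        ax.axhline(R2_THRESHOLD, color="tab:red", ls="--", lw=1)
        ax.set_ylim(0.0, 1.05)
        ax.set_title(name)
        ax.tick_params(axis="x", rotation=45)
    axes[0][0].set_ylabel("$R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
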