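"""Training of the 1D-CNN blood-gas surrogate.

The surrogate maps the 19 standardized patient-state inputs to the 4
standardized blood-gas outputs.  Inputs and outputs are both standardized
(statistics fitted on the training split only) so the heterogeneous-scale
targets — pressures in mmHg next to pH — contribute comparably to the MAE
or MSE loss.

Training uses Adam at the configured learning rate for a fixed number of
epochs with seeded shuffling; per-epoch training MAE is the running mean of
batch MAE (dropout active), validation MAE is computed in inference mode at
each epoch end.  Checkpoints capture model weights, optimizer state, the
epoch counter and the shuffling RNG, so a trial can be paused and resumed by
a hyperparameter scheduler without losing its budget accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohort import INPUT_COLUMNS, OUTPUT_COLUMNS, is_labelled, SchemaError
from .nn import Adam, ConvNet1D, loss_and_grad, mean_absolute_error
from .standardize import Standardizer

__all__ = [
    "SurrogateConfig", "TrialRecord", "DivergenceError",
    "fit_standardizer", "build_surrogate", "train_surrogate", "predict",
    "SurrogateTrial", "save_model_bundle", "load_model_bundle",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class SurrogateConfig:
    """One surrogate training configuration (the tunables plus fixed shape)."""

    learning_rate: float = 1e-4
    batch_size: int = 64
    dropout_rate: float = 0.4
    loss_id: str = "MAE"
    has_fc_layer: bool = True
    epochs: int = 50
    conv_widths: tuple[int, ...] = (64, 128, 128, 128)
    kernel_width: int = 3
    fc_width: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.loss_id not in ("MAE", "MSE"):
            raise ValueError(f"loss_id must be MAE or MSE, got {self.loss_id!r}")
        object.__setattr__(self, "conv_widths", tuple(self.conv_widths))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_widths"] = list(self.conv_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateConfig":
        d = dict(d)
        if "conv_widths" in d:
            d["conv_widths"] = tuple(d["conv_widths"])
        return cls(**d)


@dataclass
class TrialRecord:
    """History of one surrogate-training trial."""

    config: SurrogateConfig
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    epochs_consumed: int = 0
    checkpoint_ref: Any = None
    status: str = "running"   # running | complete | stopped | failed

    @property
    def final_val_mae(self) -> float:
        if not self.val_mae:
            return float("inf")
        return self.val_mae[-1]


def fit_standardizer(train: pd.DataFrame) -> tuple[Standardizer, Standardizer]:
    """Fit input and output standardizers on the training split only."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    x_std = Standardizer().fit(train[list(INPUT_COLUMNS)].to_numpy(float))
    if not is_labelled(train):
        raise SchemaError("training table must carry the 4 output columns")
    y_std = Standardizer().fit(train[list(OUTPUT_COLUMNS)].to_numpy(float))
    return x_std, y_std


def build_surrogate(config: SurrogateConfig) -> ConvNet1D:
    """Instantiate the seeded surrogate network for a configuration."""
    return ConvNet1D(
        n_features=len(INPUT_COLUMNS), n_outputs=len(OUTPUT_COLUMNS),
        conv_widths=config.conv_widths, kernel_width=config.kernel_width,
        dropout_rate=config.dropout_rate, has_fc_layer=config.has_fc_layer,
        fc_width=config.fc_width, seed=config.seed)


class SurrogateTrial:
    """A checkpointable training run — the contract the schedulers drive.

    Exposes ``train_epochs(k)``, ``get_checkpoint()`` / ``load_checkpoint()``,
    a mutable ``learning_rate`` and the accumulating :class:`TrialRecord`.
    """

    def __init__(self, config: SurrogateConfig, train: pd.DataFrame,
                 val: pd.DataFrame,
                 standardizers: tuple[Standardizer, Standardizer] | None = None):
        if not (is_labelled(train) and is_labelled(val)):
            raise SchemaError("train and val tables must be labelled")
        self.config = config
        if standardizers is None:
            standardizers = fit_standardizer(train)
        self.x_std, self.y_std = standardizers
        self._Xtr = self.x_std.transform(
            train[list(INPUT_COLUMNS)].to_numpy(float)).astype(np.float32)
        self._Ytr = self.y_std.transform(
            train[list(OUTPUT_COLUMNS)].to_numpy(float)).astype(np.float32)
        self._Xva = self.x_std.transform(
            val[list(INPUT_COLUMNS)].to_numpy(float)).astype(np.float32)
        self._Yva = self.y_std.transform(
            val[list(OUTPUT_COLUMNS)].to_numpy(float)).astype(np.float32)
        self.model = build_surrogate(config)
        self.optimizer = Adam(config.learning_rate)
        self._rng = np.random.Generator(np.random.PCG64(config.seed + 1))
        self.record = TrialRecord(config=config)

    # -- scheduler knobs ----------------------------------------------

    @property
    def learning_rate(self) -> float:
        return self.optimizer.lr

    @learning_rate.setter
    def learning_rate(self, lr: float) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.optimizer.lr = float(lr)
        self.config = replace(self.config, learning_rate=float(lr))
        self.record.config = self.config

    # -- training -----------------------------------------------------

    def _eval_mae(self, X: np.ndarray, Y: np.ndarray,
                  chunk: int = 8192) -> float:
        err = 0.0
        n = len(X)
        for i in range(0, n, chunk):
            pred = self.model.forward(X[i:i + chunk], train=False)
            err += float(np.sum(np.abs(pred - Y[i:i + chunk])))
        return err / (n * Y.shape[1])

    def train_epochs(self, k: int) -> TrialRecord:
        """Run ``k`` further epochs, appending to the trial history."""
        n = len(self._Xtr)
        bs = self.config.batch_size
        for _ in range(k):
            epoch = self.record.epochs_consumed + 1
            order = self._rng.permutation(n)
            batch_mae = []
            for i in range(0, n, bs):
                idx = order[i:i + bs]
                xb, yb = self._Xtr[idx], self._Ytr[idx]
                pred = self.model.forward(xb, train=True, dropout_rng=self._rng)
                loss, dpred = loss_and_grad(pred, yb, self.config.loss_id)
                if not np.isfinite(loss):
                    self.record.status = "failed"
                    raise DivergenceError(epoch)
                batch_mae.append(mean_absolute_error(pred, yb))
                grads = self.model.backward(dpred)
                self.optimizer.step(self.model.weights, grads)
            self.record.train_mae.append(float(np.mean(batch_mae)))
            self.record.val_mae.append(self._eval_mae(self._Xva, self._Yva))
            self.record.epochs_consumed = epoch
        return self.record

    # -- inference ----------------------------------------------------

    def predict(self, states: pd.DataFrame) -> np.ndarray:
        """De-standardized (physical-unit) predictions for a state table."""
        return predict(self.model, states, (self.x_std, self.y_std))

    # -- checkpointing ------------------------------------------------

    def get_checkpoint(self) -> dict:
        return {
            "weights": self.model.get_weights(),
            "optimizer": self.optimizer.state(),
            "epochs_consumed": self.record.epochs_consumed,
            "train_mae": list(self.record.train_mae),
            "val_mae": list(self.record.val_mae),
            "config": self.config.to_dict(),
            "rng_state": self._rng.bit_generator.state,
        }

    def load_checkpoint(self, ckpt: dict) -> None:
        cfg = SurrogateConfig.from_dict(ckpt["config"])
        if cfg.conv_widths != self.config.conv_widths or \
                cfg.has_fc_layer != self.config.has_fc_layer:
            self.config = cfg
            self.model = build_surrogate(cfg)
        self.model.set_weights(ckpt["weights"])
        self.optimizer = Adam(cfg.learning_rate)
        self.optimizer.load_state(ckpt["optimizer"])
        self.record.epochs_consumed = int(ckpt["epochs_consumed"])
        self.record.train_mae = list(ckpt["train_mae"])
        self.record.val_mae = list(ckpt["val_mae"])
        self.record.config = self.config = cfg
        self._rng.bit_generator.state = ckpt["rng_state"]


def train_surrogate(model: ConvNet1D | None, train: pd.DataFrame,
                    val: pd.DataFrame, config: SurrogateConfig,
                    standardizers: tuple[Standardizer, Standardizer] | None = None,
                    resume_from: dict | None = None) -> tuple[TrialRecord, SurrogateTrial]:
    """Train the surrogate for ``config.epochs`` epochs.

    ``resume_from`` continues a checkpoint, preserving the epoch counter.
    Returns the trial record and the live trial (for prediction/export).
    """
    trial = SurrogateTrial(config, train, val, standardizers)
    if model is not None:
        trial.model = model
    if resume_from is not None:
        trial.load_checkpoint(resume_from)
    remaining = config.epochs - trial.record.epochs_consumed
    if remaining > 0:
        trial.train_epochs(remaining)
    trial.record.status = "complete"
    trial.record.checkpoint_ref = trial.get_checkpoint()
    return trial.record, trial


def predict(model: ConvNet1D, states: pd.DataFrame,
            standardizers: tuple[Standardizer, Standardizer]) -> np.ndarray:
    """Physical-unit predictions (n, 4) for an input table; deterministic."""
    missing = [c for c in INPUT_COLUMNS if c not in states.columns]
    if missing:
        raise SchemaError(f"prediction input missing column(s): {missing}")
    x_std, y_std = standardizers
    X = x_std.transform(states[list(INPUT_COLUMNS)].to_numpy(float)).astype(np.float32)
    preds = []
    for i in range(0, len(X), 8192):
        preds.append(model.forward(X[i:i + 8192], train=False))
    if not preds:
        return np.empty((0, len(OUTPUT_COLUMNS)))
    return y_std.inverse(np.concatenate(preds, axis=0))


# ----------------------------------------------------------------------
# Model bundle (directory) persistence
# ----------------------------------------------------------------------

def save_model_bundle(path, trial: SurrogateTrial) -> None:
    """Write architecture/config, weights, standardizers and history."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.json", "w") as fh:
        json.dump(trial.config.to_dict(), fh, indent=2)
    np.savez(path / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(trial.model.get_weights())})
    with open(path / "standardizer.json", "w") as fh:
        json.dump({"inputs": trial.x_std.to_dict(),
                   "outputs": trial.y_std.to_dict()}, fh)
    hist = pd.DataFrame({
        "epoch": np.arange(1, trial.record.epochs_consumed + 1),
        "train_mae": trial.record.train_mae,
        "val_mae": trial.record.val_mae,
    })
    hist.to_csv(path / "history.csv", index=False)


def load_model_bundle(path) -> tuple[ConvNet1D, tuple[Standardizer, Standardizer],
                                     SurrogateConfig, pd.DataFrame]:
    """Load a bundle written by :func:`save_model_bundle`."""
    path = Path(path)
    with open(path / "config.json") as fh:
        config = SurrogateConfig.from_dict(json.load(fh))
    model = build_surrogate(config)
    with np.load(path / "weights.npz") as z:
        model.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    with open(path / "standardizer.json") as fh:
        d = json.load(fh)
    stds = (Standardizer.from_dict(d["inputs"]),
            Standardizer.from_dict(d["outputs"]))
    hist = pd.read_csv(path / "history.csv")
    return model, stds, config, hist
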