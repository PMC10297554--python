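"""Per-feature standardization fitted on the training split only."""

from __future__ import annotations

import numpy as np

__all__ = ["Standardizer"]

_SCALE_FLOOR = 1e-8


class Standardizer:
    """Column-wise zero-mean / unit-scale transform.

    The scale is the population standard deviation, floored at 1e-8 so a
    constant column maps to zero rather than dividing by zero.
    """

    def __init__(self, mean: np.ndarray | None = None,
                 scale: np.ndarray | None = None):
        self.mean = None if mean is None else np.asarray(mean, dtype=float)
        self.scale = None if scale is None else np.asarray(scale, dtype=float)

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit needs a 2-D array with at least 2 rows")
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd < _SCALE_FLOOR):
            import logging
            logging.getLogger(__name__).warning(
                "constant column(s) %s: scale floored at %g",
                np.nonzero(sd < _SCALE_FLOOR)[0].tolist(), _SCALE_FLOOR)
        self.scale = np.maximum(sd, _SCALE_FLOOR)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return np.asarray(Z, dtype=float) * self.scale + self.mean

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("standardizer has not been fitted")

    def to_dict(self) -> dict:
        self._require_fitted()
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]))
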