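"""Minimal NumPy neural-network core for the blood-gas surrogate.

Implements exactly the topology the surrogate needs — a stack of
same-padded 1D convolutions with ReLU, flatten, inverted dropout, an
optional fully connected hidden layer and a linear output head — with
hand-written backpropagation and an Adam optimizer.  Everything is float32
and seeded; inference is deterministic (dropout only acts in training
mode).
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet1D", "Adam", "loss_and_grad", "mean_absolute_error",
           "count_parameters"]

_DTYPE = np.float32


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


def _glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def count_parameters(n_features: int, n_outputs: int, conv_widths, kernel_width: int,
                     has_fc_layer: bool, fc_width: int) -> int:
    """Closed-form trainable-parameter count for the surrogate topology."""
    total = 0
    c_in = 1
    for f in conv_widths:
        total += kernel_width * c_in * f + f
        c_in = f
    flat = n_features * c_in
    if has_fc_layer:
        total += flat * fc_width + fc_width
        flat = fc_width
    total += flat * n_outputs + n_outputs
    return total


class ConvNet1D:
    """1D-CNN regressor: 19 features as a 1-channel sequence -> 4 outputs.

    Layer stack: ``conv(kernel_width, same, ReLU)`` for each entry of
    ``conv_widths``; flatten; dropout; optional ``dense(fc_width, ReLU)``;
    ``dense(n_outputs)`` linear.
    """

    def __init__(self, n_features: int = 19, n_outputs: int = 4,
                 conv_widths=(64, 128, 128, 128), kernel_width: int = 3,
                 dropout_rate: float = 0.0, has_fc_layer: bool = True,
                 fc_width: int = 64, seed: int = 0):
        if not conv_widths or any(int(w) <= 0 for w in conv_widths):
            raise ValueError(f"invalid conv widths {conv_widths!r}")
        if kernel_width <= 0 or fc_width <= 0:
            raise ValueError("kernel_width and fc_width must be positive")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
        self.n_features = n_features
        self.n_outputs = n_outputs
        self.conv_widths = tuple(int(w) for w in conv_widths)
        self.kernel_width = int(kernel_width)
        self.dropout_rate = float(dropout_rate)
        self.has_fc_layer = bool(has_fc_layer)
        self.fc_width = int(fc_width)

        rng = np.random.Generator(np.random.PCG64(seed))
        self.weights: list[np.ndarray] = []
        c_in = 1
        K = self.kernel_width
        for f in self.conv_widths:
            self.weights.append(_he_init(rng, K * c_in, (K * c_in, f)))
            self.weights.append(np.zeros(f, dtype=_DTYPE))
            c_in = f
        flat = n_features * c_in
        if self.has_fc_layer:
            self.weights.append(_he_init(rng, flat, (flat, self.fc_width)))
            self.weights.append(np.zeros(self.fc_width, dtype=_DTYPE))
            flat = self.fc_width
        self.weights.append(_glorot_init(rng, flat, n_outputs, (flat, n_outputs)))
        self.weights.append(np.zeros(n_outputs, dtype=_DTYPE))
        self._cache = None

    # -- plumbing ------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights))

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights]

    def set_weights(self, weights) -> None:
        if len(weights) != len(self.weights):
            raise ValueError("weight list length mismatch")
        self.weights = [np.asarray(w, dtype=_DTYPE).copy() for w in weights]

    # -- conv helpers --------------------------------------------------

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, L, C) -> (B*L, C*K) patches with same padding."""
        B, L, C = x.shape
        K = self.kernel_width
        pl, pr = (K - 1) // 2, K // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # windows: (B, L, K, C) -> (B*L, C*K) matching weight layout (K*C, F)
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
        # win: (B, L, C, K) -> reorder to (B, L, K, C)? weight rows are K*C:
        cols = win.transpose(0, 1, 3, 2).reshape(B * L, K * C)
        return np.ascontiguousarray(cols, dtype=_DTYPE)

    def _col2im(self, dcols: np.ndarray, B: int, L: int, C: int) -> np.ndarray:
        """Adjoint of :meth:`_im2col`."""
        K = self.kernel_width
        pl, pr = (K - 1) // 2, K // 2
        d = dcols.reshape(B, L, K, C)
        dxp = np.zeros((B, L + pl + pr, C), dtype=_DTYPE)
        for k in range(K):
            dxp[:, k:k + L, :] += d[:, :, k, :]
        return dxp[:, pl:pl + L, :]

    # -- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the network on ``x`` of shape (B, n_features).

        In training mode inverted dropout is applied after the flatten;
        inference never touches the dropout path.
        """
        B = x.shape[0]
        h = np.asarray(x, dtype=_DTYPE).reshape(B, self.n_features, 1)
        cache = {"cols": [], "pre": [], "shapes": []}
        wi = 0
        for f in self.conv_widths:
            Bc, L, C = h.shape
            cols = self._im2col(h)
            z = cols @ self.weights[wi] + self.weights[wi + 1]
            z = z.reshape(Bc, L, f)
            cache["cols"].append(cols)
            cache["shapes"].append((Bc, L, C))
            cache["pre"].append(z)
            h = np.maximum(z, 0.0)
            wi += 2
        flat = h.reshape(B, -1)
        cache["flat_in_shape"] = h.shape
        if train and self.dropout_rate > 0.0:
            if dropout_rng is None:
                raise ValueError("training-mode forward needs a dropout rng")
            keep = 1.0 - self.dropout_rate
            mask = (dropout_rng.random(flat.shape) < keep).astype(_DTYPE) / _DTYPE(keep)
        else:
            mask = None
        cache["mask"] = mask
        if mask is not None:
            flat = flat * mask
        cache["flat"] = flat
        if self.has_fc_layer:
            zfc = flat @ self.weights[wi] + self.weights[wi + 1]
            cache["zfc"] = zfc
            hfc = np.maximum(zfc, 0.0)
            cache["hfc"] = hfc
            wi += 2
            head_in = hfc
        else:
            head_in = flat
        cache["head_in"] = head_in
        y = head_in @ self.weights[wi] + self.weights[wi + 1]
        self._cache = cache
        return y

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. all weights for the last :meth:`forward` call."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before forward")
        grads: list[np.ndarray | None] = [None] * len(self.weights)
        wi = len(self.weights) - 2
        dy = np.asarray(dy, dtype=_DTYPE)
        grads[wi] = cache["head_in"].T @ dy
        grads[wi + 1] = dy.sum(axis=0)
        dh = dy @ self.weights[wi].T
        if self.has_fc_layer:
            wi -= 2
            dzfc = dh * (cache["zfc"] > 0)
            grads[wi] = cache["flat"].T @ dzfc
            grads[wi + 1] = dzfc.sum(axis=0)
            dh = dzfc @ self.weights[wi].T
        if cache["mask"] is not None:
            dh = dh * cache["mask"]
        dh = dh.reshape(cache["flat_in_shape"])
        for li in range(len(self.conv_widths) - 1, -1, -1):
            wi -= 2
            z = cache["pre"][li]
            dz = dh * (z > 0)
            Bc, L, C = cache["shapes"][li]
            dz_flat = dz.reshape(Bc * L, -1)
            grads[wi] = cache["cols"][li].T @ dz_flat
            grads[wi + 1] = dz_flat.sum(axis=0)
            dcols = dz_flat @ self.weights[wi].T
            dh = self._col2im(dcols, Bc, L, C)
        return grads  # type: ignore[return-value]


class Adam:
    """Adam optimizer with a mutable learning rate (for population training)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, weights: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(w) for w in weights]
            self.v = [np.zeros_like(w) for w in weights]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for w, g, m, v in zip(weights, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            w -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": None if self.m is None else [a.copy() for a in self.m],
                "v": None if self.v is None else [a.copy() for a in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = None if state["m"] is None else [a.copy() for a in state["m"]]
        self.v = None if state["v"] is None else [a.copy() for a in state["v"]]


def mean_absolute_error(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - target)))


def loss_and_grad(pred: np.ndarray, target: np.ndarray, loss_id: str):
    """Loss value and gradient w.r.t. predictions for MAE or MSE."""
    diff = pred - target
    n = diff.size
    if loss_id == "MAE":
        return float(np.mean(np.abs(diff))), np.sign(diff) / n
    if loss_id == "MSE":
        return float(np.mean(diff ** 2)), 2.0 * diff / n
    raise ValueError(f"unknown loss {loss_id!r}; expected 'MAE' or 'MSE'")
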