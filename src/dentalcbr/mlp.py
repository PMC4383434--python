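"""Single-hidden-layer perceptron trained by online backpropagation.

Architecture and training follow the classic recipe: sigmoid units
throughout, one hidden layer of 2n+1 neurons for n inputs, bias terms on
every neuron, and per-pattern weight updates with a momentum term

    dW(t) = eta * delta * activation + mu * (W(t) - W(t-1)),

where the output-layer delta is (d - y) y (1 - y) and the hidden-layer
delta backpropagates that error through the output weights.  With mu = 0
one update step is exactly a gradient-descent step on the squared error
0.5 * sum_k (d_k - y_k)^2 — the central correctness check in the test
suite compares the analytic update against finite differences.

Inputs and targets are expected in the sigmoid working range [0.2, 0.8];
:class:`RangeScaler` provides the affine map and its inverse so that
longevity targets in years can be scaled in and predictions scaled back
out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite error) at epoch {epoch}")


@dataclass
class RangeScaler:
    """Per-dimension affine map of observed [min, max] onto [0.2, 0.8].

    Constant dimensions map to the midpoint 0.5; queries outside the
    training range are clamped into [0.2, 0.8].
    """

    mins: np.ndarray
    maxs: np.ndarray
    lo: float = 0.2
    hi: float = 0.8

    @classmethod
    def fit(cls, X, lo: float = 0.2, hi: float = 0.8) -> "RangeScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise ValueError("cannot fit a scaler on empty data")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0), lo=lo, hi=hi)

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        X = np.atleast_2d(X)
        span = self.maxs - self.mins
        out = np.empty_like(X)
        const = span == 0
        safe = np.where(const, 1.0, span)
        out = self.lo + (self.hi - self.lo) * (X - self.mins) / safe
        out[:, const] = (self.lo + self.hi) / 2.0
        out = np.clip(out, self.lo, self.hi)
        return out[0] if squeeze else out

    def inverse(self, Y) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        Y = np.atleast_2d(Y)
        span = self.maxs - self.mins
        out = self.mins + (Y - self.lo) * span / (self.hi - self.lo)
        out[:, span == 0] = self.mins[span == 0]
        return out[0] if squeeze else out

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist(), "lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "RangeScaler":
        return cls(np.asarray(d["mins"], float), np.asarray(d["maxs"], float), d["lo"], d["hi"])


def scale_to_working_range(values, scaler: RangeScaler) -> np.ndarray:
    """Affine map into the sigmoid working range [0.2, 0.8]."""
    return scaler.transform(values)


def inverse_scale(values, scaler: RangeScaler) -> np.ndarray:
    return scaler.inverse(values)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPModel:
    """Weights, biases and momentum state of a 1-hidden-layer sigmoid net."""

    W_hidden: np.ndarray   # (n_hidden, n_in)
    b_hidden: np.ndarray   # (n_hidden,)
    W_out: np.ndarray      # (n_out, n_hidden)
    b_out: np.ndarray      # (n_out,)
    prev_dW_hidden: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db_hidden: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_dW_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.prev_dW_hidden is None:
            self.prev_dW_hidden = np.zeros_like(self.W_hidden)
            self.prev_db_hidden = np.zeros_like(self.b_hidden)
            self.prev_dW_out = np.zeros_like(self.W_out)
            self.prev_db_out = np.zeros_like(self.b_out)

    @property
    def n_in(self) -> int:
        return self.W_hidden.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_hidden.shape[0]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[0]

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.W_hidden.copy(), self.b_hidden.copy(), self.W_out.copy(), self.b_out.copy(),
            self.prev_dW_hidden.copy(), self.prev_db_hidden.copy(),
            self.prev_dW_out.copy(), self.prev_db_out.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "W_hidden": self.W_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "W_out": self.W_out.tolist(),
            "b_out": self.b_out.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            np.asarray(d["W_hidden"], float),
            np.asarray(d["b_hidden"], float),
            np.asarray(d["W_out"], float),
            np.asarray(d["b_out"], float),
        )


def mlp_init(n_in: int, n_out: int, seed: int = 0, n_hidden: int | None = None) -> MLPModel:
    """Fresh network with 2*n_in + 1 hidden neurons, Uniform(-0.5, 0.5) init."""
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be >= 1")
    if n_hidden is None:
        n_hidden = 2 * n_in + 1
    rng = np.random.default_rng(seed)
    return MLPModel(
        W_hidden=rng.uniform(-0.5, 0.5, size=(n_hidden, n_in)),
        b_hidden=rng.uniform(-0.5, 0.5, size=n_hidden),
        W_out=rng.uniform(-0.5, 0.5, size=(n_out, n_hidden)),
        b_out=rng.uniform(-0.5, 0.5, size=n_out),
    )


def mlp_forward(model: MLPModel, x) -> np.ndarray:
    """Sigmoid forward pass; accepts one pattern or a (n, n_in) batch."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_in:
        raise ValueError(f"expected {model.n_in} inputs, got {X.shape[1]}")
    H = _sigmoid(X @ model.W_hidden.T + model.b_hidden)
    Y = _sigmoid(H @ model.W_out.T + model.b_out)
    return Y[0] if squeeze else Y


def _update_pattern(model: MLPModel, x: np.ndarray, d: np.ndarray, eta: float, mu: float) -> None:
    """One online backprop-with-momentum update, in place."""
    h = _sigmoid(model.W_hidden @ x + model.b_hidden)
    y = _sigmoid(model.W_out @ h + model.b_out)

    delta_out = (d - y) * y * (1.0 - y)                      # (n_out,)
    # hidden delta uses the pre-update output weights
    delta_hidden = (model.W_out.T @ delta_out) * h * (1.0 - h)

    dW_out = eta * np.outer(delta_out, h) + mu * model.prev_dW_out
    db_out = eta * delta_out + mu * model.prev_db_out
    dW_hidden = eta * np.outer(delta_hidden, x) + mu * model.prev_dW_hidden
    db_hidden = eta * delta_hidden + mu * model.prev_db_hidden

    model.W_out += dW_out
    model.b_out += db_out
    model.W_hidden += dW_hidden
    model.b_hidden += db_hidden
    model.prev_dW_out = dW_out
    model.prev_db_out = db_out
    model.prev_dW_hidden = dW_hidden
    model.prev_db_hidden = db_hidden


def mlp_train(
    model: MLPModel,
    X,
    D,
    eta: float = 0.1,
    mu: float = 0.9,
    epochs: int = 1000,
    seed: int = 0,
    early_stop: tuple[float, int] | None = (0.2, 50),
) -> tuple[MLPModel, list[float]]:
    """Train in place by per-pattern backpropagation with momentum.

    ``early_stop`` is ``(validation_fraction, patience)``: that fraction of
    the patterns is held out, and training stops once the validation MSE
    has not improved for ``patience`` epochs (the best-validation weights
    are restored).  Pass ``None`` to train on everything for the full
    epoch budget.  Returns the model and the per-epoch training-MSE trace.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")  # eta=0 is a legal null update
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if len(X) == 0:
        raise ValueError("patterns must be nonempty")
    rng = np.random.default_rng(seed)

    n = len(X)
    if early_stop is not None and n >= 5:
        frac, patience = early_stop
        perm = rng.permutation(n)
        n_val = max(1, int(round(frac * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = perm, perm
    else:
        train_idx = np.arange(n)
        val_idx = None
        patience = 0

    best_val = np.inf
    best_model: MLPModel | None = None
    stall = 0
    trace: list[float] = []
    for epoch in range(epochs):
        for i in rng.permutation(train_idx):
            _update_pattern(model, X[i], D[i], eta, mu)
        Yt = mlp_forward(model, X[train_idx])
        mse = float(np.mean((D[train_idx] - Yt) ** 2))
        if not np.isfinite(mse):
            raise DivergenceError(epoch)
        trace.append(mse)
        if val_idx is not None:
            val_mse = float(np.mean((D[val_idx] - mlp_forward(model, X[val_idx])) ** 2))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_model = model.copy()
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if val_idx is not None and best_model is not None:
        model.W_hidden = best_model.W_hidden
        model.b_hidden = best_model.b_hidden
        model.W_out = best_model.W_out
        model.b_out = best_model.b_out
        model.prev_dW_hidden = best_model.prev_dW_hidden
        model.prev_db_hidden = best_model.prev_db_hidden
        model.prev_dW_out = best_model.prev_dW_out
        model.prev_db_out = best_model.prev_db_out
    return model, trace
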