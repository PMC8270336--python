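"""Feed-forward 4->n->1 surrogate with tansig hidden layer and linear output.

Inputs and response are affinely normalized onto a target interval (default
[-1, +1]) before entering the network; predictions are mapped back to natural
units.  Training is deterministic full-batch gradient descent with momentum
and a monotone acceptance rule: a step that would increase the training MSE
is rejected, the velocity reset and the step size halved, so the accepted
training-loss sequence never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable
from .errors import (
    DegenerateRangeError,
    ParseError,
    ShapeError,
    TrainingDivergenceError,
)

__all__ = [
    "AnnModel",
    "TrainReport",
    "normalize",
    "denormalize",
    "tansig",
    "forward",
    "train",
    "load_weights",
    "save_weights",
]

DEFAULT_TARGET_RANGE = (-1.0, 1.0)


def normalize(x, xmin, xmax, target=DEFAULT_TARGET_RANGE):
    """Affine map of [xmin, xmax] onto the target interval.

    With the default target this is ``2*(x - xmin)/(xmax - xmin) - 1``.
    """
    x = np.asarray(x, dtype=float)
    xmin = np.asarray(xmin, dtype=float)
    xmax = np.asarray(xmax, dtype=float)
    if np.any(xmax <= xmin):
        raise DegenerateRangeError(f"xmax must exceed xmin (got {xmin} .. {xmax})")
    lo, hi = target
    return lo + (hi - lo) * (x - xmin) / (xmax - xmin)


def denormalize(k, xmin, xmax, target=DEFAULT_TARGET_RANGE):
    """Exact inverse of :func:`normalize`."""
    k = np.asarray(k, dtype=float)
    xmin = np.asarray(xmin, dtype=float)
    xmax = np.asarray(xmax, dtype=float)
    if np.any(xmax <= xmin):
        raise DegenerateRangeError(f"xmax must exceed xmin (got {xmin} .. {xmax})")
    lo, hi = target
    return xmin + (xmax - xmin) * (k - lo) / (hi - lo)


def tansig(x):
    """Tangent-sigmoid transfer, 2/(1 + exp(-2x)) - 1 == tanh(x)."""
    return np.tanh(np.asarray(x, dtype=float))


@dataclass
class AnnModel:
    """Weights, biases and normalization bounds of the 4->n->1 network."""

    input_weights: np.ndarray   # (hidden, 4)
    input_bias: np.ndarray      # (hidden,)
    layer_weights: np.ndarray   # (hidden,)
    layer_bias: float
    input_min: np.ndarray       # (4,)
    input_max: np.ndarray       # (4,)
    response_min: float
    response_max: float
    target_range: tuple[float, float] = DEFAULT_TARGET_RANGE

    def __post_init__(self) -> None:
        self.input_weights = np.atleast_2d(np.asarray(self.input_weights, float))
        self.input_bias = np.asarray(self.input_bias, dtype=float)
        self.layer_weights = np.asarray(self.layer_weights, dtype=float)
        self.input_min = np.asarray(self.input_min, dtype=float)
        self.input_max = np.asarray(self.input_max, dtype=float)
        h = self.input_weights.shape[0]
        if self.input_weights.shape[1] != 4:
            raise ShapeError(
                f"input_weights must be (hidden, 4), got {self.input_weights.shape}"
            )
        if self.input_bias.shape != (h,) or self.layer_weights.shape != (h,):
            raise ShapeError(
                f"bias/layer weight shapes {self.input_bias.shape}/"
                f"{self.layer_weights.shape} inconsistent with hidden size {h}"
            )
        if self.input_min.shape != (4,) or self.input_max.shape != (4,):
            raise ShapeError("normalization bounds must have 4 entries")
        if np.any(self.input_max <= self.input_min) or (
            self.response_max <= self.response_min
        ):
            raise DegenerateRangeError("normalization bounds must have xmax > xmin")

    @property
    def hidden_size(self) -> int:
        return self.input_weights.shape[0]

    def covers(self, natural_point) -> bool:
        """True when the point lies inside the normalization bounds."""
        p = np.asarray(natural_point, dtype=float)
        return bool(
            np.all(p >= self.input_min - 1e-12) and np.all(p <= self.input_max + 1e-12)
        )

    def forward(self, natural_point):
        return forward(self, natural_point)

    def to_dict(self) -> dict:
        return {
            "input_weights": self.input_weights.tolist(),
            "input_bias": self.input_bias.tolist(),
            "layer_weights": self.layer_weights.tolist(),
            "layer_bias": float(self.layer_bias),
            "input_min": self.input_min.tolist(),
            "input_max": self.input_max.tolist(),
            "response_min": float(self.response_min),
            "response_max": float(self.response_max),
            "target_range": list(self.target_range),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["target_range"] = tuple(payload["target_range"])
        return cls(**payload)


def forward(model: AnnModel, natural_point):
    """Normalize -> tansig hidden layer -> linear output -> denormalize.

    Accepts a single 4-vector or an (n, 4) batch.
    """
    x = np.asarray(natural_point, dtype=float)
    scalar = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != 4:
        raise ShapeError(f"expected 4 inputs, got {x2.shape[1]}")
    k = normalize(x2, model.input_min, model.input_max, model.target_range)
    hidden = tansig(k @ model.input_weights.T + model.input_bias)
    y_norm = hidden @ model.layer_weights + model.layer_bias
    y = denormalize(
        y_norm, model.response_min, model.response_max, model.target_range
    )
    return float(y[0]) if scalar else y


@dataclass
class TrainReport:
    """Per-candidate hidden-size training outcome and the selection made."""

    candidates: list[dict] = field(default_factory=list)  # hidden/train_mse/test_mse
    selected_hidden: int = 0
    seed: int = 0
    epochs: int = 0

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "selected_hidden": self.selected_hidden,
            "seed": self.seed,
            "epochs": self.epochs,
        }


def _init_params(rng: np.random.Generator, hidden: int):
    scale = 1.0 / np.sqrt(4)
    return (
        rng.uniform(-scale, scale, size=(hidden, 4)),
        rng.uniform(-scale, scale, size=hidden),
        rng.uniform(-1.0 / np.sqrt(hidden), 1.0 / np.sqrt(hidden), size=hidden),
        float(rng.uniform(-0.1, 0.1)),
    )


def _mse(params, X, y, weight_decay=0.0):
    W, b, wo, bo = params
    loss = float(np.mean((np.tanh(X @ W.T + b) @ wo + bo - y) ** 2))
    if weight_decay:
        loss += weight_decay * float((W**2).sum() + (wo**2).sum())
    return loss


def _grads(params, X, y, weight_decay=0.0):
    W, b, wo, bo = params
    H = np.tanh(X @ W.T + b)                 # (n, h)
    out = H @ wo + bo
    err = out - y                            # (n,)
    n = len(y)
    g_wo = 2.0 * (H.T @ err) / n + 2.0 * weight_decay * wo
    g_bo = 2.0 * float(err.sum()) / n
    delta = (2.0 / n) * np.outer(err, wo) * (1.0 - H**2)  # (n, h)
    g_W = delta.T @ X + 2.0 * weight_decay * W
    g_b = delta.sum(axis=0)
    return g_W, g_b, g_wo, g_bo


def _descend(params, X, y, epochs, lr, momentum, weight_decay=0.0, val=None):
    """Momentum GD with monotone acceptance; returns params and loss trace.

    With ``val=(Xv, yv)`` the parameters at the minimum validation MSE seen
    along the accepted trajectory are returned (training completes when the
    test-set MSE reaches its minimum); otherwise the final parameters are.
    """
    loss = _mse(params, X, y, weight_decay)
    if not np.isfinite(loss):
        raise TrainingDivergenceError(
            "initial loss is not finite; try a smaller step size"
        )
    vel = [np.zeros_like(p) if isinstance(p, np.ndarray) else 0.0 for p in params]
    trace = [loss]
    best_val, best_params = np.inf, params
    if val is not None:
        best_val = float(np.mean((_predict_norm(params, val[0]) - val[1]) ** 2))
    for _ in range(epochs):
        grads = _grads(params, X, y, weight_decay)
        vel = [momentum * v - lr * g for v, g in zip(vel, grads)]
        cand = [p + v for p, v in zip(params, vel)]
        cand_loss = _mse(cand, X, y, weight_decay)
        if not np.isfinite(cand_loss):
            raise TrainingDivergenceError(
                "training diverged (non-finite loss); try a smaller step size"
            )
        if cand_loss <= loss:
            params, loss = cand, cand_loss
            lr *= 1.05
            if val is not None:
                val_mse = float(
                    np.mean((_predict_norm(params, val[0]) - val[1]) ** 2)
                )
                if val_mse < best_val:
                    best_val, best_params = val_mse, params
        else:
            vel = [np.zeros_like(p) if isinstance(p, np.ndarray) else 0.0 for p in params]
            lr *= 0.5
            if lr < 1e-14:
                break
        trace.append(loss)
    if val is not None:
        return best_params, trace
    return params, trace


def train(
    design: DesignTable,
    hidden_candidates=(10,),
    split: float = 0.8,
    seed: int = 0,
    epochs: int = 600,
    learning_rate: float = 0.1,
    momentum: float = 0.9,
    restarts: int = 3,
    shuffle: bool = False,
    weight_decay: float = 0.0,
) -> tuple[AnnModel, TrainReport]:
    """Train the surrogate on a measured design; select hidden size by test MSE.

    The train/test split follows run order by default — the first
    ``floor(split * n)`` rows train, the remainder test — matching the
    convention of the packaged study; pass ``shuffle=True`` to draw a seeded
    random split instead.  Per hidden-size candidate, ``restarts`` seeded
    initializations are trained and the best test MSE kept.  A small
    ``weight_decay`` (L2 on the weights, not the biases) curbs overfitting
    on noisy designs; the default 0 keeps exactly-representable targets
    exactly representable.  The whole procedure is a pure function of its
    arguments.
    """
    mask = design.has_response
    X_nat = design.natural[mask]
    y_nat = design.response[mask]
    n = len(y_nat)
    n_train = int(np.floor(split * n))
    if n - n_train < 2:
        raise ParseError(
            f"split {split} leaves {n - n_train} test rows; need at least 2"
        )
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(99,))
        ).permutation(n)
    idx_train, idx_test = order[:n_train], order[n_train:]

    input_min = np.array([f.low for f in design.factors])
    input_max = np.array([f.high for f in design.factors])
    # response bounds come from the training data
    resp_min, resp_max = float(y_nat.min()), float(y_nat.max())
    if resp_max <= resp_min:
        raise DegenerateRangeError("response is constant; nothing to learn")

    Xn = normalize(X_nat, input_min, input_max)
    yn = normalize(y_nat, resp_min, resp_max)
    Xtr, ytr = Xn[idx_train], yn[idx_train]
    Xte, yte = Xn[idx_test], yn[idx_test]

    yscale = (resp_max - resp_min) / 2.0  # normalized MSE -> natural-unit MSE

    report = TrainReport(seed=seed, epochs=epochs)
    best = None  # (test_mse, hidden, params)
    for ci, hidden in enumerate(hidden_candidates):
        best_h = None
        for r in range(restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, r))
            )
            params = _init_params(rng, hidden)
            params, trace = _descend(
                params, Xtr, ytr, epochs, learning_rate, momentum, weight_decay,
                val=(Xte, yte),
            )
            test_mse = float(np.mean((_predict_norm(params, Xte) - yte) ** 2))
            train_mse = float(np.mean((_predict_norm(params, Xtr) - ytr) ** 2))
            cand = (test_mse, train_mse, params)
            if best_h is None or cand[0] < best_h[0]:
                best_h = cand
        report.candidates.append(
            {
                "hidden": int(hidden),
                "train_mse": best_h[1] * yscale**2,
                "test_mse": best_h[0] * yscale**2,
            }
        )
        if best is None or best_h[0] < best[0]:
            best = (best_h[0], hidden, best_h[2])

    report.selected_hidden = int(best[1])
    W, b, wo, bo = best[2]
    model = AnnModel(
        input_weights=W,
        input_bias=b,
        layer_weights=wo,
        layer_bias=bo,
        input_min=input_min,
        input_max=input_max,
        response_min=resp_min,
        response_max=resp_max,
    )
    return model, report


def _predict_norm(params, X):
    W, b, wo, bo = params
    return np.tanh(X @ W.T + b) @ wo + bo


_WEIGHT_COLUMNS = [
    "neuron",
    "w_time",
    "w_ethanol",
    "w_ratio",
    "w_power",
    "input_bias",
    "layer_weight",
    "layer_bias",
]


def load_weights(
    path_or_frame,
    input_min,
    input_max,
    response_min: float,
    response_max: float,
) -> AnnModel:
    """Build an :class:`AnnModel` from a weight table.

    Layout: one row per hidden neuron with four input weights, the input
    bias and the hidden->output layer weight; the single output bias sits in
    the first row of the ``layer_bias`` column.  Normalization bounds are not
    part of the table and must be supplied.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = pd.read_csv(path_or_frame)
    missing = [c for c in _WEIGHT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"weight table missing columns: {missing}")
    w_cols = ["w_time", "w_ethanol", "w_ratio", "w_power"]
    sub = frame[w_cols + ["input_bias", "layer_weight"]]
    if sub.isna().any().any():
        bad = int(sub.isna().any(axis=1).idxmax())
        raise ParseError("ragged weight table", row=bad)
    return AnnModel(
        input_weights=frame[w_cols].to_numpy(float),
        input_bias=frame["input_bias"].to_numpy(float),
        layer_weights=frame["layer_weight"].to_numpy(float),
        layer_bias=float(frame["layer_bias"].iloc[0]),
        input_min=input_min,
        input_max=input_max,
        response_min=response_min,
        response_max=response_max,
    )


def save_weights(model: AnnModel, path) -> None:
    """Write the weight table (round-trips through :func:`load_weights`)."""
    h = model.hidden_size
    frame = pd.DataFrame(
        {
            "neuron": np.arange(1, h + 1),
            "w_time": model.input_weights[:, 0],
            "w_ethanol": model.input_weights[:, 1],
            "w_ratio": model.input_weights[:, 2],
            "w_power": model.input_weights[:, 3],
            "input_bias": model.input_bias,
            "layer_weight": model.layer_weights,
            "layer_bias": [model.layer_bias] + [np.nan] * (h - 1),
        }
    )
    frame.to_csv(path, index=False)
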