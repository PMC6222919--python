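"""Feed-forward neural network regression with quasi-Newton training.

A three-layer 25-H-1 network maps the encoded predictor vector to the
transformed pair resolution y = log10(R+1).  Inputs and output are
range-scaled to [0, 1] on the calibration set; the hidden layer uses a
logistic or hyperbolic-tangent activation and the output neuron is
linear.  Weights are fitted by full-batch BFGS (scipy's implementation,
with strong-Wolfe line search) on the mean squared error, with
gradients from backpropagation.  Training stops at the minimum of the
validation error: after each epoch (one quasi-Newton iteration) the
validation MSE is recorded, and learning halts once it has failed to
improve for ``patience`` consecutive epochs; the weights returned are
those of the validation-minimum epoch.

Because a single random weight initialization can land in a poor local
minimum, the selected architecture is re-trained from many independent
initializations (100 by default) and the ensemble prediction is the
arithmetic mean of the member outputs on the natural response scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AnnModel",
    "TrainConfig",
    "TrainResult",
    "EnsembleModel",
    "new_model",
    "forward",
    "train",
    "select_architecture",
    "train_ensemble",
    "predict",
    "metrics",
    "mse_and_gradient",
]

_ACTIVATIONS = ("logistic", "tanh")


@dataclass
class AnnModel:
    """One 25-H-1 network with its range-scaling parameters."""

    n_hidden: int
    activation: str  # "logistic" | "tanh"
    W_h: np.ndarray  # (H, n_in)
    b_h: np.ndarray  # (H,)
    w_out: np.ndarray  # (H,)
    b_out: float
    x_min: np.ndarray  # (n_in,) calibration-set range scaling
    x_max: np.ndarray
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("at least one hidden neuron required")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    @property
    def n_in(self) -> int:
        return self.W_h.shape[1]

    # --- weight vector packing (for the optimizer) ---

    def get_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.W_h.ravel(), self.b_h, self.w_out, [self.b_out]]
        )

    def set_weights(self, w: np.ndarray) -> None:
        H, n_in = self.n_hidden, self.n_in
        k = H * n_in
        self.W_h = w[:k].reshape(H, n_in).copy()
        self.b_h = w[k : k + H].copy()
        self.w_out = w[k + H : k + 2 * H].copy()
        self.b_out = float(w[k + 2 * H])

    # --- range scaling ---

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        rng = self.x_max - self.x_min
        rng = np.where(rng == 0, 1.0, rng)
        return (X - self.x_min) / rng

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        rng = self.y_max - self.y_min
        return (y - self.y_min) / (rng if rng != 0 else 1.0)

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return ys * (self.y_max - self.y_min) + self.y_min

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "activation": self.activation,
            "W_h": self.W_h.tolist(),
            "b_h": self.b_h.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            n_hidden=int(d["n_hidden"]),
            activation=str(d["activation"]),
            W_h=np.array(d["W_h"], dtype=float),
            b_h=np.array(d["b_h"], dtype=float),
            w_out=np.array(d["w_out"], dtype=float),
            b_out=float(d["b_out"]),
            x_min=np.array(d["x_min"], dtype=float),
            x_max=np.array(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    init_range: float = 0.1  # weights drawn uniformly in (-0.1, 0.1)
    max_epochs: int = 1000
    patience: int = 30  # epochs without validation improvement
    restarts: int = 100
    hidden_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 16)
    activations: tuple[str, ...] = ("logistic", "tanh")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restart count must be >= 1")
        if self.init_range <= 0:
            raise ValueError("init range must be positive")


@dataclass
class TrainResult:
    epochs_run: int
    best_epoch: int  # argmin of the validation trace
    train_trace: list[float]  # MSE on the scaled response, per epoch
    val_trace: list[float]
    weights: np.ndarray  # weights at the validation minimum


@dataclass
class EnsembleModel:
    members: list[AnnModel]
    train_results: list[TrainResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        archs = {(m.n_hidden, m.activation) for m in self.members}
        if len(archs) > 1:
            raise ValueError("ensemble members must share one architecture")

    def to_json(self, path) -> None:
        payload = {
            "members": [m.to_dict() for m in self.members],
            "best_epochs": [r.best_epoch for r in self.train_results],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(members=[AnnModel.from_dict(d) for d in payload["members"]])


def new_model(
    n_hidden: int,
    activation: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
) -> AnnModel:
    """Zero-weight network with range scaling set from the calibration set."""
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n_in = X_cal.shape[1]
    return AnnModel(
        n_hidden=n_hidden,
        activation=activation,
        W_h=np.zeros((n_hidden, n_in)),
        b_h=np.zeros(n_hidden),
        w_out=np.zeros(n_hidden),
        b_out=0.0,
        x_min=X_cal.min(axis=0),
        x_max=X_cal.max(axis=0),
        y_min=float(y_cal.min()),
        y_max=float(y_cal.max()),
    )


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(a)
    return 1.0 / (1.0 + np.exp(-a))


def _act_prime_from_value(h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - h**2
    return h * (1.0 - h)


def _forward_scaled(model: AnnModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = Z @ model.W_h.T + model.b_h
    Hv = _act(A, model.activation)
    out = Hv @ model.w_out + model.b_out
    return out, Hv


def forward(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Network response on the natural scale; X rows are 25-vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_in:
        raise ValueError(f"expected {model.n_in} inputs, got {X.shape[1]}")
    out, _ = _forward_scaled(model, model.scale_x(X))
    return model.unscale_y(out)


def mse_and_gradient(
    model: AnnModel, w: np.ndarray, Z: np.ndarray, ys: np.ndarray
) -> tuple[float, np.ndarray]:
    """MSE on the scaled response and its gradient w.r.t. the weights.

    The gradient is the analytic backpropagation result; a finite-
    difference check of this function is part of the test suite.
    """
    H, n_in = model.n_hidden, model.n_in
    k = H * n_in
    W_h = w[:k].reshape(H, n_in)
    b_h = w[k : k + H]
    w_out = w[k + H : k + 2 * H]
    b_out = w[k + 2 * H]

    A = Z @ W_h.T + b_h
    Hv = _act(A, model.activation)
    out = Hv @ w_out + b_out
    resid = out - ys
    n = len(ys)
    loss = float(np.mean(resid**2))

    coef = 2.0 / n
    g_wout = coef * (Hv.T @ resid)
    g_bout = coef * np.sum(resid)
    G = (resid[:, None] * w_out[None, :]) * _act_prime_from_value(
        Hv, model.activation
    )  # (n, H)
    g_Wh = coef * (G.T @ Z)
    g_bh = coef * G.sum(axis=0)

    grad = np.concatenate([g_Wh.ravel(), g_bh, g_wout, [g_bout]])
    return loss, grad


def train(
    model: AnnModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    seed: int | None = None,
) -> TrainResult:
    """Fit the network by BFGS with validation-based early stopping.

    Mutates ``model`` in place, leaving it at the weights of the
    validation-minimum epoch.  Fully deterministic given ``seed``.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    Z_tr = model.scale_x(np.asarray(X_train, dtype=float))
    ys_tr = model.scale_y(np.asarray(y_train, dtype=float))
    Z_val = model.scale_x(np.asarray(X_val, dtype=float))
    ys_val = model.scale_y(np.asarray(y_val, dtype=float))

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_weights = model.n_hidden * (model.n_in + 2) + 1
    w0 = rng.uniform(-config.init_range, config.init_range, size=n_weights)

    def val_mse(w: np.ndarray) -> float:
        model.set_weights(w)
        out, _ = _forward_scaled(model, Z_val)
        return float(np.mean((out - ys_val) ** 2))

    train_trace = [mse_and_gradient(model, w0, Z_tr, ys_tr)[0]]
    val_trace = [val_mse(w0)]
    best = {"epoch": 0, "val": val_trace[0], "w": w0.copy()}
    state = {"since_best": 0, "epochs": 0}

    def callback(wk: np.ndarray) -> None:
        state["epochs"] += 1
        tr = mse_and_gradient(model, wk, Z_tr, ys_tr)[0]
        vl = val_mse(wk)
        train_trace.append(tr)
        val_trace.append(vl)
        if vl < best["val"]:
            best.update(epoch=state["epochs"], val=vl, w=wk.copy())
            state["since_best"] = 0
        else:
            state["since_best"] += 1
            if state["since_best"] >= config.patience:
                raise StopIteration

    minimize(
        lambda w: mse_and_gradient(model, w, Z_tr, ys_tr),
        w0,
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": config.max_epochs, "gtol": 1e-8},
    )

    model.set_weights(best["w"])
    return TrainResult(
        epochs_run=state["epochs"],
        best_epoch=best["epoch"],
        train_trace=train_trace,
        val_trace=val_trace,
        weights=best["w"].copy(),
    )


def select_architecture(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> tuple[int, str, list[dict]]:
    """Exhaustive grid scan; returns (H, activation, selection table).

    One network is trained per (H, activation) cell and the cell with
    the lowest validation MSE wins.  The full table is returned for
    reporting.
    """
    if not config.hidden_grid or not config.activations:
        raise ValueError("architecture grid must be nonempty")
    X_cal = np.vstack([X_train, X_val])
    y_cal = np.concatenate([y_train, y_val])
    table = []
    best = None
    for H in config.hidden_grid:
        for act in config.activations:
            model = new_model(H, act, X_cal, y_cal)
            result = train(model, X_train, y_train, X_val, y_val, config,
                           seed=config.seed)
            val = result.val_trace[result.best_epoch]
            table.append(
                {"n_hidden": H, "activation": act,
                 "val_mse": val, "epochs": result.best_epoch}
            )
            if best is None or val < best[2]:
                best = (H, act, val)
    return best[0], best[1], table


def train_ensemble(
    n_hidden: int,
    activation: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> EnsembleModel:
    """Re-train one architecture from ``config.restarts`` initializations.

    Member seeds are master seed + member index, so the full ensemble is
    reproducible from the master seed alone.
    """
    X_cal = np.vstack([X_train, X_val])
    y_cal = np.concatenate([y_train, y_val])
    members, results = [], []
    for k in range(config.restarts):
        model = new_model(n_hidden, activation, X_cal, y_cal)
        results.append(
            train(model, X_train, y_train, X_val, y_val, config,
                  seed=config.seed + k)
        )
        members.append(model)
    return EnsembleModel(members=members, train_results=results)


def predict(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Ensemble prediction: mean of member outputs on the natural scale."""
    preds = np.stack([forward(m, X) for m in ensemble.members])
    return preds.mean(axis=0)


def metrics(predictions: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """(R-squared, standard error = root mean squared residual)."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape or len(targets) < 2:
        raise ValueError("predictions and targets must share length >= 2")
    ss_tot = float(np.sum((targets - targets.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R-squared undefined for zero-variance targets")
    ss_res = float(np.sum((predictions - targets) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    se = float(np.sqrt(np.mean((predictions - targets) ** 2)))
    return r2, se
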