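"""Single-hidden-layer feed-forward network with linear transfer functions.

A purelin-purelin network — linear hidden and output neurons — is an
affine map, which matches the Beer-Lambert linearity of absorbance in
concentration. Training uses Levenberg-Marquardt on the full weight
Jacobian of the calibration residuals, with the validation set as an
early-stopping monitor: training halts when the validation RMSE has
risen for ``patience`` consecutive epochs while the calibration RMSE
kept falling, and the weights from the epoch with the lowest validation
RMSE are returned. Inputs and targets are scaled to [-1, 1] by the
calibration min-max before training; the scaling is baked into the
model so ``forward`` accepts raw absorbance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError, TrainingFailureError

__all__ = ["AnnConfig", "AnnModel", "init_network", "forward", "train_lm", "scan_hidden"]

_MU_MAX = 1e10


@dataclass(frozen=True)
class AnnConfig:
    """Network and training hyperparameters.

    ``mu_init``/``mu_dec``/``mu_inc`` are the Levenberg-Marquardt
    damping coefficient and its multiplicative decrease/increase on
    accepted/rejected steps (0.001, 0.001, 100 by default). mu_dec of
    0.001 is aggressive; it is kept configurable.
    """

    hidden_neurons: int = 5
    transfer: str = "purelin-purelin"
    mu_init: float = 0.001
    mu_dec: float = 0.001
    mu_inc: float = 100.0
    max_epochs: int = 1000
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ConfigError("hidden_neurons must be >= 1")
        if self.mu_init <= 0 or not (0 < self.mu_dec < 1 < self.mu_inc):
            raise ConfigError("require mu_init > 0 and 0 < mu_dec < 1 < mu_inc")
        if self.transfer != "purelin-purelin":
            raise ConfigError(
                "only the purelin-purelin (linear-linear) transfer pair is supported"
            )


@dataclass
class AnnModel:
    """Weights, scaling and training traces of a fitted network."""

    w1: np.ndarray            # (h, d)
    b1: np.ndarray            # (h,)
    w2: np.ndarray            # (h,)
    b2: float
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    y_min: float = -1.0
    y_max: float = 1.0
    cal_rmse_trace: list = field(default_factory=list)
    val_rmse_trace: list = field(default_factory=list)
    mu_trace: list = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden_neurons(self) -> int:
        return self.w1.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "w1": self.w1.tolist(),
                    "b1": self.b1.tolist(),
                    "w2": self.w2.tolist(),
                    "b2": float(self.b2),
                    "x_min": None if self.x_min is None else self.x_min.tolist(),
                    "x_max": None if self.x_max is None else self.x_max.tolist(),
                    "y_min": float(self.y_min),
                    "y_max": float(self.y_max),
                    "cal_rmse_trace": list(self.cal_rmse_trace),
                    "val_rmse_trace": list(self.val_rmse_trace),
                },
                fh,
            )


def init_network(n_inputs: int, config: AnnConfig) -> AnnModel:
    """Seeded uniform(-0.5, 0.5) initialization of all weights and biases."""
    if n_inputs < 1:
        raise ConfigError("n_inputs must be >= 1")
    rng = np.random.default_rng(config.seed)
    h = config.hidden_neurons
    return AnnModel(
        w1=rng.uniform(-0.5, 0.5, size=(h, n_inputs)),
        b1=rng.uniform(-0.5, 0.5, size=h),
        w2=rng.uniform(-0.5, 0.5, size=h),
        b2=float(rng.uniform(-0.5, 0.5)),
    )


def _scale_x(model: AnnModel, X: np.ndarray) -> np.ndarray:
    if model.x_min is None:
        return X
    span = np.where(model.x_max > model.x_min, model.x_max - model.x_min, 1.0)
    return 2.0 * (X - model.x_min) / span - 1.0


def _unscale_y(model: AnnModel, y_scaled: np.ndarray) -> np.ndarray:
    if model.y_max == model.y_min:
        return np.full_like(y_scaled, model.y_min)
    return (y_scaled + 1.0) * (model.y_max - model.y_min) / 2.0 + model.y_min


def _scale_y(model: AnnModel, y: np.ndarray) -> np.ndarray:
    span = model.y_max - model.y_min if model.y_max > model.y_min else 1.0
    return 2.0 * (y - model.y_min) / span - 1.0


def _forward_scaled(w1, b1, w2, b2, Xs) -> np.ndarray:
    return (Xs @ w1.T + b1) @ w2 + b2


def forward(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the network on raw absorbance rows (returns ug/mL)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ShapeError(
            f"X has {X.shape[1]} columns, network expects {model.n_inputs}"
        )
    return _unscale_y(model, _forward_scaled(model.w1, model.b1, model.w2, model.b2, _scale_x(model, X)))


def _jacobian(w1, b1, w2, Xs) -> np.ndarray:
    """Jacobian of residuals w.r.t. the packed parameter vector.

    Parameter order: w1 (row-major), b1, w2, b2. For a linear network
    d r_i/d w1[j,k] = w2[j] * x[i,k], d r_i/d b1[j] = w2[j],
    d r_i/d w2[j] = hidden[i,j], d r_i/d b2 = 1.
    """
    n, d = Xs.shape
    h = w1.shape[0]
    hidden = Xs @ w1.T + b1  # (n, h)
    J = np.empty((n, h * d + h + h + 1))
    J[:, : h * d] = np.einsum("j,ik->ijk", w2, Xs).reshape(n, h * d)
    J[:, h * d : h * d + h] = np.broadcast_to(w2, (n, h))
    J[:, h * d + h : h * d + 2 * h] = hidden
    J[:, -1] = 1.0
    return J


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, h, d):
    w1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = float(theta[-1])
    return w1, b1, w2, b2


def train_lm(
    model: AnnModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: AnnConfig,
) -> AnnModel:
    """Levenberg-Marquardt training with validation-based early stopping.

    Each epoch solves (J'J + mu*I) delta = -J'r on the scaled
    calibration data; an accepted step (SSE decreases) multiplies mu by
    ``mu_dec``, a rejected one by ``mu_inc`` with a retry. Training
    stops at ``max_epochs``, when mu exceeds its cap with no acceptable
    step (converged), or when the validation RMSE has risen for
    ``patience`` consecutive epochs while calibration RMSE fell. The
    returned model carries the weights of the best-validation epoch.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if X_cal.shape[0] == 0 or X_val.shape[0] == 0:
        raise ShapeError("calibration and validation sets must be nonempty")
    if X_cal.shape[1] != X_val.shape[1] or X_cal.shape[1] != model.n_inputs:
        raise ShapeError("column counts of X_cal, X_val and the network must match")

    # freeze min-max scaling from the calibration set
    model.x_min = X_cal.min(axis=0)
    model.x_max = X_cal.max(axis=0)
    model.y_min = float(y_cal.min())
    model.y_max = float(y_cal.max())
    Xs, ys = _scale_x(model, X_cal), _scale_y(model, y_cal)
    Xvs = _scale_x(model, X_val)

    h, d = model.hidden_neurons, model.n_inputs
    theta = _pack(model.w1, model.b1, model.w2, model.b2)
    mu = config.mu_init

    def unscaled_rmse(th, Xq, yq):
        pred = _unscale_y(model, _forward_scaled(*_unpack(th, h, d), Xq))
        return float(np.sqrt(np.mean((pred - yq) ** 2)))

    def sse(th):
        r = _forward_scaled(*_unpack(th, h, d), Xs) - ys
        return float(r @ r)

    cal_trace = [unscaled_rmse(theta, Xs, y_cal)]
    val_trace = [unscaled_rmse(theta, Xvs, y_val)]
    mu_trace: list[float] = []
    # best checkpoint considers trained epochs only, never the random init
    best_theta, best_val = theta.copy(), np.inf
    rising = 0

    current_sse = sse(theta)
    for _epoch in range(config.max_epochs):
        w1, b1, w2, b2 = _unpack(theta, h, d)
        r = _forward_scaled(w1, b1, w2, b2, Xs) - ys
        J = _jacobian(w1, b1, w2, Xs)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        all_singular = True
        while mu <= _MU_MAX:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), -Jtr)
            except np.linalg.LinAlgError:
                # singular at this damping (overparameterized net, tiny mu):
                # treat as a rejected step and retry with more damping
                mu *= config.mu_inc
                continue
            if not np.all(np.isfinite(delta)):
                mu *= config.mu_inc
                continue
            all_singular = False
            candidate = theta + delta
            cand_sse = sse(candidate)
            if cand_sse < current_sse:
                theta, current_sse = candidate, cand_sse
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            if all_singular:
                raise TrainingFailureError(
                    "damped normal equations singular up to the mu cap"
                )
            break  # mu capped with no downhill step: converged

        mu_trace.append(mu)
        cal_rmse = unscaled_rmse(theta, Xs, y_cal)
        val_rmse = unscaled_rmse(theta, Xvs, y_val)
        if val_rmse < best_val:
            best_val, best_theta = val_rmse, theta.copy()
        if val_rmse > val_trace[-1] and cal_rmse < cal_trace[-1]:
            rising += 1
        else:
            rising = 0
        cal_trace.append(cal_rmse)
        val_trace.append(val_rmse)
        if rising >= config.patience:
            break

    model.w1, model.b1, model.w2, model.b2 = _unpack(best_theta, h, d)
    model.cal_rmse_trace = cal_trace
    model.val_rmse_trace = val_trace
    model.mu_trace = mu_trace
    return model


def scan_hidden(
    X_cal, y_cal, X_val, y_val, candidates, config: AnnConfig
):
    """Train one network per hidden-neuron count; pick the best.

    Returns ``(chosen_count, {count: validation RMSE})``; ties — exact
    or within numerical noise of the minimum — go to the smallest
    network.
    """
    candidates = list(candidates)
    if not candidates:
        raise ConfigError("candidates must be nonempty")
    report: dict[int, float] = {}
    for hcount in candidates:
        cfg = AnnConfig(
            hidden_neurons=hcount,
            transfer=config.transfer,
            mu_init=config.mu_init,
            mu_dec=config.mu_dec,
            mu_inc=config.mu_inc,
            max_epochs=config.max_epochs,
            patience=config.patience,
            seed=config.seed,
        )
        net = train_lm(init_network(np.asarray(X_cal).shape[1], cfg), X_cal, y_cal, X_val, y_val, cfg)
        pred = forward(net, X_val)
        report[hcount] = float(np.sqrt(np.mean((pred - np.asarray(y_val, dtype=float)) ** 2)))
    m = min(report.values())
    tol = 1e-9 + 1e-6 * m
    best = min(k for k in report if report[k] <= m + tol)
    return best, report
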