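"""PLS-1 regression (NIPALS) with leave-one-out latent-variable selection.

One model per analyte: the spectral matrix X is regressed on a single
concentration vector y. NIPALS with deflation of X only is used; for a
single response the power iteration collapses, so each component is
exact, but the iteration guard is kept for safety. Data are
mean-centered internally and the centering terms are stored on the
model, so ``predict`` works on raw absorbance.

The number of latent variables (LVs) is chosen by leave-one-out
cross-validation: the LV count with the lowest RMSECV wins, ties going
to the smaller model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import mean_center
from .errors import DeflationCollapseError, InvalidParameterError, ShapeError

__all__ = [
    "PlsModel",
    "CvCurve",
    "fit_pls1",
    "predict",
    "loo_rmsecv",
    "select_n_lv",
    "fit_with_loo",
]

_MAX_ITER = 500
_TOL = 1e-12


@dataclass(frozen=True)
class PlsModel:
    """Fitted PLS-1 model for one analyte."""

    n_lv: int
    x_weights: np.ndarray      # (p, A) normalized weight vectors
    x_loadings: np.ndarray     # (p, A)
    x_scores: np.ndarray       # (n, A)
    y_loadings: np.ndarray     # (A,)
    regression_vector: np.ndarray  # (p,)
    x_mean: np.ndarray         # (p,)
    y_mean: float
    analyte: str = ""

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "n_lv": int(self.n_lv),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            x_scores=np.asarray(d["x_scores"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            analyte=d.get("analyte", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PlsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CvCurve:
    """RMSECV (ug/mL) as a function of the LV count 1..A_max."""

    n_lv_grid: np.ndarray
    rmsecv: np.ndarray

    def __post_init__(self) -> None:
        if len(self.n_lv_grid) != len(self.rmsecv):
            raise ShapeError("n_lv_grid and rmsecv must have equal length")


def _nipals_components(Xc: np.ndarray, yc: np.ndarray, a_max: int, strict: bool = True):
    """Extract up to ``a_max`` NIPALS PLS-1 components from centered data.

    Returns (W, P, T, q, n_extracted). Stops early (without error) when
    y has no remaining covariance with X; when X itself is exhausted
    before a_max components, raises DeflationCollapseError if ``strict``
    else returns the components extracted so far.
    """
    n, p = Xc.shape
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    q = np.zeros(a_max)
    Xd = Xc.copy()
    x_scale = np.linalg.norm(Xc) + 1e-300
    scale = max(1.0, x_scale * max(np.linalg.norm(yc), 1.0))

    for a in range(a_max):
        # Single-response NIPALS: the power iteration on (w, t, q) reaches
        # its fixed point in one pass, so w = Xd'y directly. _MAX_ITER/_TOL
        # remain as guards should a multi-response variant reuse this core.
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-10 * scale:
            if np.linalg.norm(Xd) < 1e-10 * x_scale and strict:
                raise DeflationCollapseError(
                    f"X rank exhausted after {a} components (requested {a_max})"
                )
            # y orthogonal to remaining X (constant y, or non-strict mode
            # with X rank exhausted): stop cleanly
            return W[:, :a], P[:, :a], T[:, :a], q[:a], a
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _TOL * x_scale**2:
            raise DeflationCollapseError(
                f"degenerate score vector at component {a + 1}"
            )
        p_vec = Xd.T @ t / tt
        q_a = yc @ t / tt
        Xd -= np.outer(t, p_vec)
        W[:, a], P[:, a], T[:, a], q[a] = w, p_vec, t, q_a
    return W, P, T, q, a_max


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int, analyte: str = "") -> PlsModel:
    """Fit a PLS-1 model with ``n_lv`` latent variables.

    Deterministic (no random initialization). Raises
    :class:`DeflationCollapseError` if X is rank-deficient relative to
    the requested LV count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise InvalidParameterError(
            f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    W, P, T, q, _ = _nipals_components(Xc, yc, n_lv)
    b = _regression_vector(W, P, q)
    return PlsModel(
        n_lv=n_lv,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        regression_vector=b,
        x_mean=x_mean,
        y_mean=y_mean,
        analyte=analyte,
    )


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations: y_mean + (X - x_mean) @ b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1]} columns, model was trained on {model.x_mean.shape[0]}"
        )
    return model.y_mean + (X - model.x_mean) @ model.regression_vector


def _truncated_regression_vectors(X: np.ndarray, y: np.ndarray, a_max: int):
    """Regression vectors for every truncation 1..a_max from one fit.

    Rank deficiency is tolerated: if fewer than a_max components are
    extractable the last vector is reused for the larger truncations
    (the model cannot grow past the effective rank).

    Returns (list of b, x_mean, y_mean).
    """
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    W, P, _, q, a_got = _nipals_components(Xc, yc, a_max, strict=False)
    bs = [_regression_vector(W[:, :a], P[:, :a], q[:a]) for a in range(1, a_got + 1)]
    while len(bs) < a_max:
        bs.append(bs[-1] if bs else np.zeros(X.shape[1]))
    return bs, x_mean, y_mean


def loo_rmsecv(X: np.ndarray, y: np.ndarray, a_max: int) -> CvCurve:
    """Leave-one-out RMSECV for LV counts 1..a_max.

    For each left-out sample a single NIPALS decomposition to a_max
    components supplies predictions for every truncated model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InvalidParameterError("leave-one-out needs at least 3 samples")
    if not 1 <= a_max <= min(n - 2, p):
        raise InvalidParameterError(
            f"a_max must be in [1, min(n-2, p)] = [1, {min(n - 2, p)}]"
        )
    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        bs, x_mean, y_mean = _truncated_regression_vectors(X[keep], y[keep], a_max)
        for a_idx, b in enumerate(bs):
            pred = y_mean + (X[i] - x_mean) @ b
            press[a_idx] += (pred - y[i]) ** 2
    return CvCurve(n_lv_grid=np.arange(1, a_max + 1), rmsecv=np.sqrt(press / n))


def select_n_lv(curve: CvCurve) -> int:
    """LV count with the lowest RMSECV; ties broken toward fewer LVs."""
    if len(curve.rmsecv) == 0:
        raise InvalidParameterError("empty CV curve")
    return int(curve.n_lv_grid[int(np.argmin(curve.rmsecv))])


def fit_with_loo(X, y, a_max: int = 10, analyte: str = ""):
    """Convenience: LOO-select the LV count, then fit. Returns (model, curve).

    If the selected count exceeds the effective rank of the full data
    (possible on noiseless low-rank spectra, where the CV curve is flat
    beyond the rank), the fit falls back to the largest extractable count.
    """
    a_max = min(a_max, np.asarray(X).shape[0] - 2, np.asarray(X).shape[1])
    curve = loo_rmsecv(X, y, a_max)
    n_lv = select_n_lv(curve)
    while n_lv > 1:
        try:
            return fit_pls1(X, y, n_lv, analyte=analyte), curve
        except DeflationCollapseError:
            n_lv -= 1
    return fit_pls1(X, y, 1, analyte=analyte), curve
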