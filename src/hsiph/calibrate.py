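"""Calibration models and evaluation metrics.

Two regressors map a sample spectrum to a scalar pH:

* **PLS1** — iterative NIPALS partial least squares for a single response.
  Spectra are mean-centred; each latent variable (LV) is the direction of
  maximal covariance with the residual response, and the model exposes the
  weights w_a, loadings p_a, y-loadings q_a and scores t_a that downstream
  VIP scoring needs.  The number of LVs is chosen by k-fold cross-validated
  RMSE.

* **BPNN** — a three-layer feed-forward network (tanh hidden layer, linear
  output) trained by full-batch backpropagation (Adam).  Inputs are
  standardised, the response min-max scaled.  Hidden-layer width candidates
  follow the heuristic b = round(sqrt(m + n)) + a with a = 1..10 for m
  inputs and n outputs; the candidate with minimal validation RMSE wins.

Models are scored by the Pearson correlation between predicted and
reference pH (r_c on the calibration set, r_p on the prediction set) and
the root mean square errors RMSEC / RMSEP.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "PLSModel",
    "fit_pls",
    "choose_n_components",
    "BPNNTrainConfig",
    "BPNNModel",
    "fit_bpnn",
    "hidden_node_candidates",
    "select_bpnn_nodes",
    "EvaluationReport",
    "evaluate_model",
    "reduction_percentage",
    "percent_decrease",
]


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Mean-centred PLS1 regression with A latent variables."""

    n_components: int
    x_weights: np.ndarray    # (p, A), unit columns
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    x_scores: np.ndarray     # (n, A), training scores
    coef: np.ndarray         # (p,)
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_inputs(self) -> int:
        return self.coef.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"model expects {self.n_inputs} bands, got {X.shape[1]}")
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict_by_deflation(self, X: np.ndarray) -> np.ndarray:
        """Prediction through the LV deflation recursion (equals ``predict``)."""
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        yhat = np.full(Xc.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xc @ self.x_weights[:, a]
            yhat += self.y_loadings[a] * t
            Xc = Xc - np.outer(t, self.x_loadings[:, a])
        return yhat


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS with mean-centring.

    If the residual rank is exhausted before ``n_components`` LVs, the model
    is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; PLS undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(np.abs(Xc).max(), 1.0)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    used = 0
    for a in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12 * scale * max(np.abs(yc).max(), 1e-30):
            warnings.warn(
                f"rank exhausted after {used} latent variables "
                f"(requested {n_components}); model truncated")
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-30:
            warnings.warn(
                f"degenerate score at LV {a + 1}; model truncated at {used}")
            break
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
        used += 1
    W, P, Q, T = W[:, :used], P[:, :used], Q[:used], T[:, :used]
    # B = W (P'W)^-1 q : regression vector on centred X
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(used, W, P, Q, T, coef, x_mean, y_mean)


def choose_n_components(
    X: np.ndarray,
    y: np.ndarray,
    max_a: int,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the LV count minimising k-fold RMSECV; returns (A, rmsecv curve)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, {n}]")
    max_feasible = min(max_a, X.shape[1], n - int(np.ceil(n / folds)) - 1)
    if max_feasible < 1:
        raise ValueError("too few samples for cross-validation")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    press = np.zeros(max_feasible)
    for tr, te in kf.split(X):
        model = fit_pls(X[tr], y[tr], max_feasible)
        Xc = X[te] - model.x_mean
        yhat = np.full(len(te), model.y_mean)
        for a in range(model.n_components):
            t = Xc @ model.x_weights[:, a]
            yhat += model.y_loadings[a] * t
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
            press[a] += float(np.sum((y[te] - yhat) ** 2))
        # if the fold model truncated early, the last attainable prediction
        # stands in for the deeper component counts
        for a in range(model.n_components, max_feasible):
            press[a] += float(np.sum((y[te] - yhat) ** 2))
    rmsecv = np.sqrt(press / n)
    return int(np.argmin(rmsecv)) + 1, rmsecv


# ---------------------------------------------------------------------------
# BPNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BPNNTrainConfig:
    epochs: int = 1500
    learning_rate: float = 0.01
    seed: int = 0


@dataclass
class BPNNModel:
    """Three-layer feed-forward net: standardised inputs, tanh hidden, linear out."""

    n_hidden: int
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_min: float
    y_max: float
    config: BPNNTrainConfig
    loss_curve: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(0))

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        H = np.tanh(Xs @ self.W1 + self.b1)
        return H @ self.W2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"model expects {self.n_inputs} bands, got {X.shape[1]}")
        z = self._forward((X - self.x_mean) / self.x_sd)
        return self.y_min + (self.y_max - self.y_min) * z.ravel()


def fit_bpnn(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    train_config: BPNNTrainConfig = BPNNTrainConfig(),
) -> BPNNModel:
    """Train the network by full-batch backpropagation (Adam on MSE).

    Deterministic for a fixed seed.  Raises if the loss turns non-finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; scaling undefined")
    n, m = X.shape
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    y_min, y_max = float(y.min()), float(y.max())
    ys = (y - y_min) / (y_max - y_min)

    rng = np.random.default_rng(train_config.seed)
    s1 = 1.0 / np.sqrt(m)
    W1 = rng.uniform(-s1, s1, (m, n_hidden))
    b1 = rng.uniform(-s1, s1, n_hidden)
    s2 = 1.0 / np.sqrt(n_hidden)
    W2 = rng.uniform(-s2, s2, (n_hidden, 1))
    b2 = float(rng.uniform(-s2, s2))

    params = [W1, b1, W2, np.array([b2])]
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = train_config.learning_rate
    losses = np.empty(train_config.epochs)
    for epoch in range(train_config.epochs):
        A = Xs @ params[0] + params[1]
        H = np.tanh(A)
        z = (H @ params[2]).ravel() + params[3][0]
        err = z - ys
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise RuntimeError(
                "BPNN training diverged (non-finite loss); reduce learning rate")
        losses[epoch] = loss
        g_z = 2.0 * err / n                       # dL/dz, (n,)
        gW2 = H.T @ g_z[:, None]
        gb2 = np.array([g_z.sum()])
        gH = np.outer(g_z, params[2].ravel())
        gA = gH * (1.0 - H ** 2)
        gW1 = Xs.T @ gA
        gb1 = gA.sum(axis=0)
        for i, g in enumerate((gW1, gb1, gW2, gb2)):
            mom[i] = beta1 * mom[i] + (1 - beta1) * g
            vel[i] = beta2 * vel[i] + (1 - beta2) * g ** 2
            mhat = mom[i] / (1 - beta1 ** (epoch + 1))
            vhat = vel[i] / (1 - beta2 ** (epoch + 1))
            params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
    return BPNNModel(
        n_hidden=n_hidden, W1=params[0], b1=params[1], W2=params[2],
        b2=float(params[3][0]), x_mean=x_mean, x_sd=x_sd,
        y_min=y_min, y_max=y_max, config=train_config, loss_curve=losses,
    )


def hidden_node_candidates(m: int, n: int) -> list[int]:
    """Hidden-layer width candidates: round(sqrt(m + n)) + a, a = 1..10."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    base = round(np.sqrt(m + n))
    return [base + a for a in range(1, 11)]


def select_bpnn_nodes(
    X: np.ndarray,
    y: np.ndarray,
    validation: tuple[np.ndarray, np.ndarray],
    n_outputs: int = 1,
    train_config: BPNNTrainConfig = BPNNTrainConfig(),
) -> tuple[BPNNModel, int, dict]:
    """Train one network per hidden-width candidate; keep the best on validation.

    Returns (best model, chosen width, {width: validation RMSE}).
    """
    X = np.asarray(X, dtype=float)
    X_val, y_val = validation
    candidates = hidden_node_candidates(X.shape[1], n_outputs)
    scores: dict[int, float] = {}
    best: tuple[float, int, BPNNModel] | None = None
    for b in candidates:
        cfg = BPNNTrainConfig(train_config.epochs, train_config.learning_rate,
                              train_config.seed + b)
        model = fit_bpnn(X, y, b, cfg)
        rmse = float(np.sqrt(np.mean((model.predict(X_val) - y_val) ** 2)))
        scores[b] = rmse
        if best is None or rmse < best[0]:
            best = (rmse, b, model)
    assert best is not None
    return best[2], best[1], scores


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    r_c: float
    rmsec: float
    r_p: float
    rmsep: float
    n_cal: int
    n_pred: int

    def to_row(self) -> dict:
        """One row in the study's metric-table layout."""
        return {
            "r_c": self.r_c, "RMSEC": self.rmsec,
            "r_p": self.r_p, "RMSEP": self.rmsep,
            "n_cal": self.n_cal, "n_pred": self.n_pred,
        }


def _pearson(pred: np.ndarray, ref: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        warnings.warn("constant values; correlation undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(pred, ref)[0, 1])


def evaluate_model(model, X_cal, y_cal, X_pred, y_pred) -> EvaluationReport:
    """Pearson r and RMSE on calibration and prediction sets."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_cal.size == 0 or y_pred.size == 0:
        raise ValueError("empty evaluation set")
    p_cal = model.predict(np.asarray(X_cal, dtype=float))
    p_prd = model.predict(np.asarray(X_pred, dtype=float))
    return EvaluationReport(
        r_c=_pearson(p_cal, y_cal),
        rmsec=float(np.sqrt(np.mean((p_cal - y_cal) ** 2))),
        r_p=_pearson(p_prd, y_pred),
        rmsep=float(np.sqrt(np.mean((p_prd - y_pred) ** 2))),
        n_cal=int(y_cal.size),
        n_pred=int(y_pred.size),
    )


def reduction_percentage(n_full: int, n_selected: int) -> float:
    """Percent reduction in band count: 100 * (1 - n_selected / n_full)."""
    if n_full <= 0 or n_selected <= 0:
        raise ValueError("band counts must be positive")
    if n_selected > n_full:
        raise ValueError("n_selected exceeds n_full")
    return 100.0 * (1.0 - n_selected / n_full)


def percent_decrease(reference: float, value: float) -> float:
    """Percent decrease of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - value) / reference
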