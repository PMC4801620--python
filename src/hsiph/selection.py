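"""Wavelength selection: successive projections, random frog, VIP.

Full NIR spectra are collinear and redundant; these three selectors pick
small informative band subsets for calibration.

* **SPA** builds candidate chains by repeatedly choosing the band whose
  column has the largest norm in the orthogonal complement of the bands
  already chosen, then scores every (start, length) chain by
  cross-validated multiple linear regression and keeps the global best.

* **Random frog** runs a reversible stochastic search over band subsets:
  each iteration proposes a grown/shrunk candidate subset (dimension drawn
  around the current size), scores it by cross-validated PLS, and accepts
  good moves always, bad moves with a small probability.  The per-band
  inclusion frequency over N iterations is its selection probability; the
  final subset is the probability top-k minimising RMSECV.

* **VIP** ranks bands by their variable-importance-in-projection score from
  a fitted PLS model,
  v_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ),
  SSY_a = q_a^2 t_a't_a, and keeps bands with v_j above a threshold
  (default 1.21).  The mean squared VIP score is exactly 1.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibrate import PLSModel, fit_pls

__all__ = [
    "SelectionResult",
    "VIPResult",
    "FrogTrace",
    "spa_projection_chain",
    "spa_select",
    "vip_scores",
    "vip_select",
    "random_frog",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    method: str                     # "SPA" | "RF" | "VIP"
    selected_indices: np.ndarray    # unique, sorted band indices
    selected_wavelengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size and (len(np.unique(idx)) != idx.size or np.any(np.diff(idx) < 0)):
            raise ValueError("selected indices must be unique and sorted")
        self.selected_indices = idx
        self.selected_wavelengths = np.asarray(self.selected_wavelengths, dtype=float)

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_indices": self.selected_indices.tolist(),
            "selected_wavelengths": self.selected_wavelengths.tolist(),
            "config": self.config_echo,
        }


def _wavelengths_for(indices: np.ndarray, wavelengths) -> np.ndarray:
    if wavelengths is None:
        return np.asarray(indices, dtype=float)
    return np.asarray(wavelengths, dtype=float)[indices]


# ---------------------------------------------------------------------------
# successive projections algorithm
# ---------------------------------------------------------------------------

def spa_projection_chain(X: np.ndarray, start: int, k: int,
                         center: bool = True) -> list[int]:
    """Ordered SPA chain of ``k`` bands beginning at column ``start``.

    Columns are mean-centred internally (``center=False`` works on the raw
    columns; centring costs one rank).  At each step the unselected column
    with the largest norm after projection onto the orthogonal complement of
    the selected columns' span is appended; ties break to the lowest index.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start column {start} out of range")
    k_max = min(n - 1, p) if center else min(n, p)
    if k < 1 or k > k_max:
        raise ValueError(f"k must be in [1, {k_max}]")
    R = X - X.mean(axis=0) if center else X.copy()  # columns deflated in place
    scale = np.linalg.norm(R) + 1e-300
    chain = [start]
    selected = np.zeros(p, dtype=bool)
    selected[start] = True
    for _ in range(k - 1):
        v = R[:, chain[-1]].copy()
        nv = np.linalg.norm(v)
        if nv < 1e-12 * scale:
            raise ValueError(
                f"rank exhausted after {len(chain)} bands; k={k} infeasible")
        v /= nv
        R = R - np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))  # argmax takes the lowest index on ties
        if norms[nxt] < 1e-12 * scale:
            raise ValueError(
                f"rank exhausted after {len(chain)} bands; k={k} infeasible")
        chain.append(nxt)
        selected[nxt] = True
    return chain


def _cv_mlr_rmse(X: np.ndarray, y: np.ndarray, folds: np.ndarray) -> float:
    """RMSE of multiple linear regression under pre-assigned CV folds."""
    press = 0.0
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        A = np.column_stack([np.ones(tr.sum()), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(te.sum()), X[te]]) @ coef
        press += float(np.sum((y[te] - pred) ** 2))
    return float(np.sqrt(press / len(y)))


def _assign_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    return folds[rng.permutation(n)]


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    k_min: int = 5,
    k_max: int = 30,
    folds: int = 5,
    seed: int = 0,
    wavelengths=None,
    starts=None,
) -> SelectionResult:
    """SPA band selection: best (start, k) chain by cross-validated MLR RMSE.

    Defaults mirror the study configuration (chain lengths 5-30).  The full
    RMSE surface is kept in ``diagnostics['rmse_surface']``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("y is constant; selection undefined")
    feasible = min(n - 1 - int(np.ceil(n / folds)), p)
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > feasible:
        raise ValueError(
            f"k_max={k_max} exceeds the feasible rank {feasible} "
            f"for n={n}, p={p}, folds={folds}")
    starts = range(p) if starts is None else list(starts)
    fold_ids = _assign_folds(n, folds, seed)
    surface = np.full((p, k_max + 1), np.nan)
    best: tuple[float, int, list[int]] | None = None
    for s in starts:
        try:
            chain = spa_projection_chain(X, s, k_max)
        except ValueError:
            continue  # rank exhausted from this start
        for k in range(k_min, k_max + 1):
            rmse = _cv_mlr_rmse(X[:, chain[:k]], y, fold_ids)
            surface[s, k] = rmse
            if best is None or rmse < best[0]:
                best = (rmse, s, chain[:k])
    if best is None:
        raise ValueError("no feasible SPA chain found")
    rmse, s, subset = best
    idx = np.sort(np.asarray(subset, dtype=int))
    return SelectionResult(
        method="SPA",
        selected_indices=idx,
        selected_wavelengths=_wavelengths_for(idx, wavelengths),
        diagnostics={"rmse_surface": surface, "best_start": s,
                     "best_k": len(subset), "best_rmse": rmse,
                     "chain_order": list(subset)},
        config_echo={"k_min": k_min, "k_max": k_max, "folds": folds, "seed": seed},
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclass
class VIPResult:
    scores: np.ndarray
    threshold: float = 1.21
    n_components_used: int = 0


def vip_scores(pls: PLSModel, threshold: float = 1.21) -> VIPResult:
    """Variable-importance-in-projection scores of a fitted PLS model."""
    if pls.n_components < 1:
        raise ValueError("PLS model has no components")
    W = pls.x_weights                      # unit columns
    T = pls.x_scores
    q = pls.y_loadings
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("na,na->a", T, T)   # q_a^2 t_a' t_a
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    v = np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())
    return VIPResult(scores=v, threshold=threshold,
                     n_components_used=pls.n_components)


def vip_select(vip: VIPResult, wavelengths=None) -> SelectionResult:
    """Bands with VIP score above the threshold (empty selection is allowed)."""
    idx = np.flatnonzero(vip.scores > vip.threshold)
    if idx.size == 0:
        warnings.warn(f"no VIP score exceeds threshold {vip.threshold}; "
                      "empty selection")
    return SelectionResult(
        method="VIP",
        selected_indices=idx,
        selected_wavelengths=_wavelengths_for(idx, wavelengths),
        diagnostics={"scores": vip.scores,
                     "n_components_used": vip.n_components_used},
        config_echo={"threshold": vip.threshold},
    )


# ---------------------------------------------------------------------------
# random frog
# ---------------------------------------------------------------------------

@dataclass
class FrogTrace:
    selection_probabilities: np.ndarray
    n_iterations: int
    seed: int
    chosen_model_size: int
    rmsecv_by_topk: dict = field(default_factory=dict)
    n_accepted: int = 0
    n_rejected_failures: int = 0


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                max_components: int) -> float:
    press = 0.0
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        a = min(max_components, X.shape[1], int(tr.sum()) - 1)
        model = fit_pls(X[tr], y[tr], a)
        press += float(np.sum((y[te] - model.predict(X[te])) ** 2))
    return float(np.sqrt(press / len(y)))


def random_frog(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 10_000,
    seed: int = 0,
    q_init: int = 10,
    theta: float = 0.3,
    eta: float = 0.1,
    max_components: int = 10,
    cv_folds: int = 4,
    k_cap: int = 30,
    wavelengths=None,
) -> tuple[FrogTrace, SelectionResult]:
    """Random-frog band selection.

    ``q_init`` is the initial subset size, ``theta`` the relative SD of the
    proposed-dimension jump, ``eta`` the acceptance factor for worse
    candidates, ``max_components`` the inner-PLS LV cap.  Cross-validation
    folds are re-drawn for every candidate evaluation: a fixed partition
    would let the stochastic search overfit that one split and drift toward
    bloated subsets.  The final size-selection curve uses one common
    partition so the top-k scores are comparable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if p < 2:
        raise ValueError("need at least 2 candidate bands")
    rng = np.random.default_rng(seed)
    q_hi = min(p, n - int(np.ceil(n / cv_folds)) - 1)
    q_init = int(np.clip(q_init, 1, q_hi))

    def rmsecv(subset: np.ndarray) -> float:
        folds = _assign_folds(n, cv_folds, int(rng.integers(2 ** 31)))
        return _pls_rmsecv(X[:, subset], y, folds, max_components)

    def coef_rank(subset: np.ndarray) -> np.ndarray:
        """Subset ordered by decreasing |PLS regression coefficient|."""
        a = min(max_components, subset.size, n - 1)
        model = fit_pls(X[:, subset], y, a)
        return subset[np.argsort(-np.abs(model.coef), kind="stable")]

    current = np.sort(rng.choice(p, q_init, replace=False))
    rmse_cur = rmsecv(current)
    counts = np.zeros(p)
    n_accepted = 0
    n_failures = 0
    for _ in range(n_iterations):
        q_cur = current.size
        q_star = int(np.clip(round(rng.normal(q_cur, theta * q_cur)), 1, q_hi))
        try:
            if q_star < q_cur:
                candidate = np.sort(coef_rank(current)[:q_star])
            elif q_star > q_cur:
                comp = np.setdiff1d(np.arange(p), current, assume_unique=False)
                n_extra = min(3 * (q_star - q_cur), comp.size)
                pool = np.concatenate([current,
                                       rng.choice(comp, n_extra, replace=False)])
                candidate = np.sort(coef_rank(pool)[:min(q_star, pool.size)])
            else:
                # same dimension: swap one band to keep the chain mixing
                comp = np.setdiff1d(np.arange(p), current)
                candidate = current.copy()
                if comp.size:
                    candidate[rng.integers(q_cur)] = rng.choice(comp)
                candidate = np.sort(candidate)
            rmse_cand = rmsecv(candidate)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failures += 1
            logger.debug("random frog candidate rejected: %s", exc)
            counts[current] += 1
            continue
        if rmse_cand <= rmse_cur or rng.random() < eta * rmse_cur / rmse_cand:
            current, rmse_cur = candidate, rmse_cand
            n_accepted += 1
        counts[current] += 1

    probs = counts / n_iterations
    ranking = np.lexsort((np.arange(p), -probs))  # probability desc, index asc
    final_folds = _assign_folds(n, cv_folds, int(rng.integers(2 ** 31)))
    rmse_topk: dict[int, float] = {}
    best_k, best_rmse = 1, np.inf
    for k in range(1, min(k_cap, q_hi) + 1):
        r = _pls_rmsecv(X[:, np.sort(ranking[:k])], y, final_folds,
                        max_components)
        rmse_topk[k] = r
        if r < best_rmse:
            best_k, best_rmse = k, r
    idx = np.sort(ranking[:best_k])
    trace = FrogTrace(
        selection_probabilities=probs, n_iterations=n_iterations, seed=seed,
        chosen_model_size=best_k, rmsecv_by_topk=rmse_topk,
        n_accepted=n_accepted, n_rejected_failures=n_failures,
    )
    result = SelectionResult(
        method="RF",
        selected_indices=idx,
        selected_wavelengths=_wavelengths_for(idx, wavelengths),
        diagnostics={"probabilities": probs, "rmsecv_by_topk": rmse_topk,
                     "best_rmsecv": best_rmse},
        config_echo={"n_iterations": n_iterations, "seed": seed,
                     "q_init": q_init, "theta": theta, "eta": eta,
                     "max_components": max_components, "cv_folds": cv_folds},
    )
    return trace, result
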