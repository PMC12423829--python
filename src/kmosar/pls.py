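"""Partial least squares regression with the full QSAR validation suite.

A NIPALS latent-variable decomposition fitted on centered (optionally
autoscaled) data, with the statistics QSAR practitioners report:

    calibration   R^2 = 1 - SSE/SSY,  RMSEC = sqrt(SSE/n),
                  SEC = sqrt(SSE/(n - nLV - 1)),
                  F = [(SSY - SSE)/nLV] / [SSE/(n - nLV - 1)]
    leave-one-out PRESS = sum (y_i - yhat_(i))^2,  Q^2 = 1 - PRESS/SSY,
                  RMSECV = sqrt(PRESS/n)
    external      R^2_pred = 1 - sum (y_t - yhat_t)^2 / sum (y_t - ybar_train)^2

plus y-randomization (chance-correlation control) and correlation-ranked
forward variable selection scored by LOO Q^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "PLSModelSummary",
    "fit_pls",
    "calibrate_stats",
    "loo_cv",
    "cross_validate",
    "external_validation",
    "y_randomization",
    "select_variables",
    "choose_n_lv",
    "coefficient_map",
]


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, n_lv) NIPALS weights W
    loadings: np.ndarray      # (p, n_lv) X loadings P
    y_loadings: np.ndarray    # (n_lv,) q
    coefficients: np.ndarray  # (p,) regression vector in original X space
    intercept: float
    feature_names: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return X @ self.coefficients + self.intercept


class RankError(ValueError):
    pass


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def fit_pls(X, y, n_lv: int, scale: bool = False) -> PLSModel:
    """Fit a single-response PLS model with ``n_lv`` latent variables.

    X is centered (and autoscaled when ``scale=True``) internally.  NIPALS:
    for each component, weight w ∝ X'y, score t = Xw, X loading p = X't/t't,
    y loading q = y't/t't, then deflation of X (and y).  The regression
    vector in original variable space is b = W (P'W)^-1 q.

    Raises :class:`RankError` when ``n_lv`` exceeds the rank of the centered
    X, reporting the rank.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(0)
    x_scale = X.std(0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xc = (X - x_mean) / x_scale
    rank = np.linalg.matrix_rank(Xc)
    if n_lv > rank:
        raise RankError(f"n_lv={n_lv} exceeds rank(X)={rank}")
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise RankError(
                f"residual covariance vanished at component {a + 1}; "
                f"effective rank of the signal is {a}"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a

    b_scaled = W @ np.linalg.solve(P.T @ W, q)
    coefficients = b_scaled / x_scale
    intercept = y_mean - float(x_mean @ coefficients)
    return PLSModel(
        n_lv=n_lv, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        weights=W, loadings=P, y_loadings=q, coefficients=coefficients,
        intercept=intercept, feature_names=names,
    )


@dataclass
class PLSModelSummary:
    n_lv: int
    r2: float
    rmsec: float
    sec: float | None
    press_cv: float
    q2: float
    rmsecv: float
    f_stat: float | None
    r2_pred: float | None = None
    coefficients: dict | None = None

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def calibrate_stats(model: PLSModel, X, y) -> dict:
    """R², RMSEC, SEC and F for a fitted model on its calibration data."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(X)
    n = len(y)
    sse = float(((y - yhat) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / ssy
    rmsec = math.sqrt(sse / n)
    dof = n - model.n_lv - 1
    if dof <= 0 or sse == 0:
        sec = math.sqrt(sse / dof) if dof > 0 else None
        f_stat = None if (dof <= 0 or sse == 0) else ((ssy - sse) / model.n_lv) / (sse / dof)
    else:
        sec = math.sqrt(sse / dof)
        f_stat = ((ssy - sse) / model.n_lv) / (sse / dof)
    return {"r2": r2, "rmsec": rmsec, "sec": sec, "f_stat": f_stat,
            "sse": sse, "ssy": ssy}


def cross_validate(X, y, n_lv: int, leave_out: int = 1, scale: bool = False) -> dict:
    """Leave-``leave_out``-out cross-validation (LOO by default).

    For every held-out block the model is refit from scratch and the block
    predicted; PRESS = Σ(y_i − ŷ_(i))², Q² = 1 − PRESS/SSY, RMSECV =
    sqrt(PRESS/n).
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_lv + 2:
        raise ValueError(f"need n >= n_lv + 2 (n={n}, n_lv={n_lv})")
    yhat_out = np.empty(n)
    for start in range(0, n, leave_out):
        held = np.arange(start, min(start + leave_out, n))
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        try:
            m = fit_pls(X[mask], y[mask], n_lv, scale=scale)
        except RankError as err:
            raise RankError(f"refit failed for held-out block {held}: {err}") from err
        yhat_out[held] = m.predict(X[held])
    press = float(((y - yhat_out) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    return {
        "press_cv": press,
        "q2": 1.0 - press / ssy,
        "rmsecv": math.sqrt(press / n),
        "predictions": yhat_out,
    }


def loo_cv(X, y, n_lv: int, scale: bool = False) -> dict:
    """Leave-one-out cross-validation; see :func:`cross_validate`."""
    return cross_validate(X, y, n_lv, leave_out=1, scale=scale)


def external_validation(model: PLSModel, X_test, y_test, y_train_mean: float) -> float:
    """R²_pred = 1 − Σ(y_t − ŷ_t)² / Σ(y_t − ȳ_train)²."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) == 0:
        raise ValueError("empty test set")
    yhat = model.predict(X_test)
    num = float(((y_test - yhat) ** 2).sum())
    den = float(((y_test - y_train_mean) ** 2).sum())
    return 1.0 - num / den


def y_randomization(X, y, n_lv: int, n_permutations: int = 50, seed: int = 0) -> np.ndarray:
    """Q² under permuted responses — the chance-correlation null.

    A sound model's real Q² should sit far above this distribution; values
    near or below zero for the permuted fits indicate the model cannot reach
    its statistics by chance.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    out = np.empty(n_permutations)
    for k in range(n_permutations):
        out[k] = cross_validate(X, rng.permutation(y), n_lv)["q2"]
    return out


def choose_n_lv(X, y, max_lv: int = 10, scale: bool = False) -> tuple[int, dict]:
    """Number of latent variables maximising LOO Q² (capped at ``max_lv``)."""
    X_arr = _as_matrix(X)
    rank = np.linalg.matrix_rank(X_arr - X_arr.mean(0))
    best = None
    scan = {}
    for a in range(1, min(max_lv, rank, len(X_arr) - 2) + 1):
        q2 = cross_validate(X_arr, y, a, scale=scale)["q2"]
        scan[a] = q2
        if best is None or q2 > scan[best]:
            best = a
    if best is None:
        raise RankError("no admissible number of latent variables")
    return best, scan


class SelectionError(ValueError):
    pass


def select_variables(
    X: pd.DataFrame,
    y,
    max_features: int = 15,
    pool_size: int = 80,
    max_lv: int = 5,
    min_gain: float = 1e-4,
    scale: bool = False,
) -> tuple[list, list[dict]]:
    """Correlation-ranked forward selection scored by LOO Q².

    Columns are ranked by |Pearson correlation with y| and the top
    ``pool_size`` form the candidate pool.  The search is greedy best-first:
    at each step every remaining pool member is trialled in the current
    subset and the one with the largest LOO Q² is kept, stopping when no
    candidate improves Q² by at least ``min_gain`` or ``max_features`` are
    kept.  Deterministic for fixed inputs.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xv = X.to_numpy(dtype=float)
    yc = y - y.mean()
    sy = math.sqrt((yc * yc).sum())
    corr = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        xc = Xv[:, j] - Xv[:, j].mean()
        sx = math.sqrt((xc * xc).sum())
        corr[j] = abs((xc * yc).sum() / (sx * sy)) if sx > 0 and sy > 0 else 0.0
    pool = sorted(range(Xv.shape[1]), key=lambda j: (-corr[j], j))[:pool_size]

    kept: list[int] = []
    best_q2 = -np.inf
    trace: list[dict] = []
    while len(kept) < max_features:
        best_j, best_trial_q2 = None, best_q2
        for j in pool:
            if j in kept:
                continue
            trial = kept + [j]
            n_lv = min(max_lv, len(trial), len(y) - 2)
            try:
                q2 = cross_validate(Xv[:, trial], y, n_lv, scale=scale)["q2"]
            except RankError:
                continue
            if q2 > best_trial_q2 + min_gain:
                best_j, best_trial_q2 = j, q2
        if best_j is None:
            break
        kept.append(best_j)
        best_q2 = best_trial_q2
        trace.append({"added": X.columns[best_j], "q2": best_q2, "n_kept": len(kept)})
    if not kept:
        raise SelectionError(f"no variable subset selected; best Q² seen: {best_q2}")
    return [X.columns[j] for j in kept], trace


def coefficient_map(model: PLSModel, grid) -> dict[str, np.ndarray]:
    """Re-index PLS coefficients onto the energy grid, split by field type.

    The model must have been fitted on field-descriptor columns named
    (grid_idx, energy_type).  Returns {"LJ": array, "C": array} of shape
    ``grid.dims`` with zeros where no descriptor survived pruning/selection.
    """
    if model.feature_names is None:
        raise ValueError("model lacks feature names; fit on a DataFrame of field columns")
    maps = {"LJ": np.zeros(grid.n_points), "C": np.zeros(grid.n_points)}
    for name, b in zip(model.feature_names, model.coefficients):
        try:
            idx, etype = name
            idx = int(idx)
        except (TypeError, ValueError) as err:
            raise ValueError(f"feature {name!r} is not a (grid_idx, type) column") from err
        if etype not in maps:
            raise ValueError(f"unknown energy type {etype!r}")
        if not 0 <= idx < grid.n_points:
            raise ValueError(f"grid index {idx} outside grid with {grid.n_points} points")
        maps[etype][idx] = b
    return {k: v.reshape(grid.dims) for k, v in maps.items()}


def summarize_model(
    model: PLSModel, X, y, X_test=None, y_test=None, scale: bool = False
) -> PLSModelSummary:
    """Assemble the full calibration + validation statistics table."""
    cal = calibrate_stats(model, X, y)
    cv = cross_validate(X, y, model.n_lv, scale=scale)
    r2_pred = None
    if X_test is not None and y_test is not None and len(np.atleast_1d(y_test)):
        r2_pred = external_validation(model, X_test, y_test, model.y_mean)
    names = model.feature_names or [f"x{j}" for j in range(len(model.coefficients))]
    return PLSModelSummary(
        n_lv=model.n_lv, r2=cal["r2"], rmsec=cal["rmsec"], sec=cal["sec"],
        press_cv=cv["press_cv"], q2=cv["q2"], rmsecv=cv["rmsecv"],
        f_stat=cal["f_stat"], r2_pred=r2_pred,
        coefficients={str(n): float(b) for n, b in zip(names, model.coefficients)},
    )
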