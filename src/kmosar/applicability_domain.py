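"""Leverage-based applicability domain analysis.

The leverage of a compound, h_i = x_i' (X'X)^-1 x_i with X the training
descriptor matrix, measures its distance from the training data in
descriptor space; predictions for compounds with h above the warning
threshold h* = 3p/n (p descriptors, n training compounds) are flagged as
extrapolations.  With p = 8 descriptors and n = 109 training compounds the
threshold is 0.220.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LeverageResult", "leverage", "ad_report", "RankDeficiencyError"]


class RankDeficiencyError(ValueError):
    pass


@dataclass
class LeverageResult:
    table: pd.DataFrame   # columns: h, set_label, in_domain
    h_star: float
    p: int
    n_train: int

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["threshold"] = self.h_star
        out.to_csv(path, index_label="molecule_id")


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Name columns involved in exact linear dependence (via QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [str(names[j]) for j in piv[rank:]]


def leverage(
    train_matrix: pd.DataFrame,
    query_matrix: pd.DataFrame | None = None,
    scale: bool = False,
) -> LeverageResult:
    """Compute leverages for training and (optionally) query compounds.

    Columns are used as emitted by the descriptor pipeline (unscaled) by
    default; set ``scale=True`` to autoscale on training statistics.  The
    training matrix must be full column rank; otherwise the collinear
    columns are named in the error.
    """
    Xt = train_matrix.to_numpy(dtype=float)
    names = list(train_matrix.columns)
    n, p = Xt.shape
    if query_matrix is not None and list(query_matrix.columns) != names:
        raise ValueError("query columns do not match training columns")
    if scale:
        mu, sd = Xt.mean(0), Xt.std(0, ddof=0)
        sd[sd == 0] = 1.0
        Xt = (Xt - mu) / sd
    if np.linalg.matrix_rank(Xt) < p:
        bad = _collinear_columns(Xt, names)
        raise RankDeficiencyError(
            f"training matrix is rank deficient; collinear columns: {bad}"
        )
    xtx_inv = np.linalg.inv(Xt.T @ Xt)
    h_star = 3.0 * p / n

    rows = {}
    h_train = np.einsum("ij,jk,ik->i", Xt, xtx_inv, Xt)
    for idx, h in zip(train_matrix.index, h_train):
        rows[idx] = (float(h), "train")
    if query_matrix is not None and len(query_matrix):
        Xq = query_matrix.to_numpy(dtype=float)
        if scale:
            Xq = (Xq - mu) / sd
        h_query = np.einsum("ij,jk,ik->i", Xq, xtx_inv, Xq)
        for idx, h in zip(query_matrix.index, h_query):
            rows[idx] = (float(h), "test")

    table = pd.DataFrame(
        {"h": [v[0] for v in rows.values()],
         "set_label": [v[1] for v in rows.values()]},
        index=list(rows.keys()),
    )
    table["in_domain"] = table["h"] < h_star
    return LeverageResult(table=table, h_star=h_star, p=p, n_train=n)


def ad_report(result: LeverageResult) -> dict:
    """In/out-of-domain counts per set plus the outliers, largest h first."""
    t = result.table
    report = {"h_star": result.h_star, "p": result.p, "n_train": result.n_train}
    for label in ("train", "test"):
        sub = t[t.set_label == label]
        if len(sub) == 0:
            continue
        report[f"n_{label}"] = int(len(sub))
        report[f"in_domain_{label}"] = int(sub.in_domain.sum())
        report[f"outliers_{label}"] = [
            (str(i), float(h))
            for i, h in sub[~sub.in_domain]["h"].sort_values(ascending=False).items()
        ]
    return report
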