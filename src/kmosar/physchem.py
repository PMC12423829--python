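"""Physicochemical profiling: the eight standard drug-likeness descriptors
and their Pearson correlation structure with potency.

Descriptors: Crippen Log P, molecular weight, ring count (SSSR), aromatic
ring count, H-bond acceptors/donors, rotatable bonds, and topological polar
surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, rdBase
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "PHYSCHEM_COLUMNS",
    "compute_physchem",
    "pearson",
    "correlation_matrix",
    "summarize",
    "ZeroVarianceError",
]

PHYSCHEM_COLUMNS = ("logp", "mw", "nrings", "nar", "hba", "hbd", "nrb", "tpsa")


class ZeroVarianceError(ValueError):
    """Pearson r is undefined for a constant vector (not zero)."""


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    return {
        "logp": Crippen.MolLogP(mol),
        "mw": Descriptors.MolWt(mol),
        "nrings": rdMolDescriptors.CalcNumRings(mol),
        "nar": rdMolDescriptors.CalcNumAromaticRings(mol),
        "hba": rdMolDescriptors.CalcNumHBA(mol),
        "hbd": rdMolDescriptors.CalcNumHBD(mol),
        "nrb": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
    }


def compute_physchem(records) -> pd.DataFrame:
    """Eight-descriptor table, one row per compound.

    ``records`` may be curated CompoundRecords or anything with
    ``molecule_id``/``smiles`` attributes or keys.  Unparseable structures
    are reported in the frame's ``attrs["failures"]`` and skipped; the
    toolkit version is recorded in ``attrs["toolkit"]``.
    """
    rows, index, failures = [], [], []
    for rec in records:
        mid = getattr(rec, "molecule_id", None) or rec["molecule_id"]
        smi = getattr(rec, "smiles", None) or rec["smiles"]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            failures.append(mid)
            continue
        rows.append(_descriptor_row(mol))
        index.append(mid)
    table = pd.DataFrame(rows, index=pd.Index(index, name="molecule_id"))
    table.attrs["toolkit"] = f"RDKit {rdBase.rdkitVersion}"
    table.attrs["failures"] = failures
    return table


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation undefined for a zero-variance vector")
    return float((dx * dy).sum() / (sx * sy))


def correlation_matrix(table: pd.DataFrame, pic50: pd.Series | None = None) -> pd.DataFrame:
    """Symmetric Pearson matrix over descriptor columns (plus pIC50 if given)."""
    data = table.copy()
    if pic50 is not None:
        data["pic50"] = np.asarray(pic50, dtype=float)
    values = data.to_numpy(dtype=float)
    n = values.shape[1]
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = pearson(values[:, i], values[:, j])
    return pd.DataFrame(r, index=data.columns, columns=data.columns)


def correlation_long(corr: pd.DataFrame) -> pd.DataFrame:
    """Long-format (pair, r, |r|) export for bubble-heatmap plotting."""
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append({"x": a, "y": b, "r": corr.loc[a, b], "abs_r": abs(corr.loc[a, b])})
    return pd.DataFrame(rows)


@dataclass
class DescriptorSummary:
    stats: pd.DataFrame                  # mean/min/max per descriptor, 3 d.p.
    bins: dict[str, pd.DataFrame]        # per descriptor: bin edges + class counts


def summarize(
    table: pd.DataFrame,
    activity_class: pd.Series | None = None,
    n_bins: int = 10,
) -> DescriptorSummary:
    """Per-descriptor mean/min/max plus class-conditional histogram bins."""
    if table.empty:
        raise ValueError("cannot summarize an empty descriptor table")
    stats = pd.DataFrame(
        {
            "mean": table.mean().round(3),
            "min": table.min().round(3),
            "max": table.max().round(3),
        }
    )
    bins: dict[str, pd.DataFrame] = {}
    if activity_class is not None:
        cls = np.asarray(activity_class, dtype=int)
        for col in table.columns:
            x = table[col].to_numpy(dtype=float)
            edges = np.histogram_bin_edges(x, bins=n_bins)
            active, _ = np.histogram(x[cls == 1], bins=edges)
            inactive, _ = np.histogram(x[cls == 0], bins=edges)
            bins[col] = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:],
                 "active": active, "inactive": inactive}
            )
    return DescriptorSummary(stats=stats, bins=bins)
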