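"""Curation of raw bioassay activity tables into a modeling-ready dataset.

Raw IC50 tables pulled from activity databases mix replicate measurements,
censored values recorded as text ("">10000""), missing entries and broken
structure annotations.  Curation canonicalises structures, removes rows that
cannot support regression/classification, merges concordant replicates, and
converts IC50 (nM) to pIC50 = -log10(IC50 in M).  Compounds at or above the
potency cutoff (default pIC50 7.6) are labelled active.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import rdBase

__all__ = [
    "CompoundRecord",
    "CurationLog",
    "CurationError",
    "curate",
    "ic50_to_pic50",
    "assign_class",
    "records_to_frame",
]

ACTIVITY_CUTOFF = 7.6  # pIC50; >= cutoff is "active"

_RANGE_RE = re.compile(r"^\s*[<>~≥≤]|^\s*\d+(\.\d+)?\s*[-–]\s*\d")


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class CompoundRecord:
    """One curated molecule."""

    molecule_id: str
    smiles: str                 # canonical SMILES
    ic50: float                 # nM
    pic50: float
    activity_class: int         # 1 = active (pic50 >= cutoff)
    family_label: str | None = None


@dataclass
class CurationLog:
    """Every removal, with its reason, in input order."""

    canonicalization: str = f"RDKit {rdBase.rdkitVersion} default canonical SMILES"
    removals: list[tuple[str, str]] = field(default_factory=list)

    def add(self, molecule_id: str, reason: str) -> None:
        self.removals.append((str(molecule_id), reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removals:
            key = reason.split(":")[0]
            out[key] = out.get(key, 0) + 1
        return out

    def to_text(self) -> str:
        lines = [f"# curation log ({self.canonicalization})"]
        lines += [f"{mid}\t{reason}" for mid, reason in self.removals]
        return "\n".join(lines) + "\n"


def ic50_to_pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar); input in nM."""
    if not (ic50_nM > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    return -math.log10(ic50_nM * 1e-9)


def assign_class(pic50: float, cutoff: float = ACTIVITY_CUTOFF) -> int:
    """1 (active) iff pic50 >= cutoff, else 0."""
    if not np.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    return 1 if pic50 >= cutoff else 0


def _parse_ic50(value) -> tuple[float | None, str | None]:
    """Return (numeric nM value, removal reason or None)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None, "missing IC50"
    if isinstance(value, str):
        s = value.strip()
        if not s:
            return None, "missing IC50"
        if _RANGE_RE.match(s):
            return None, f"ranged IC50: {s!r}"
        try:
            num = float(s)
        except ValueError:
            return None, f"unparseable IC50: {s!r}"
    else:
        num = float(value)
        if math.isnan(num):
            return None, "missing IC50"
    if num <= 0:
        return None, f"non-positive IC50: {num}"
    return num, None


def curate(
    raw: pd.DataFrame,
    cutoff: float = ACTIVITY_CUTOFF,
    id_column: str = "molecule_id",
    smiles_column: str = "smiles",
    ic50_column: str = "ic50_nM",
    family_column: str = "family",
) -> tuple[list[CompoundRecord], CurationLog]:
    """Refine a raw activity table into curated records.

    Removes rows with missing/ranged/unparseable IC50 and unparseable SMILES,
    then deduplicates on canonical structure.  Replicates whose IC50 values
    all agree within one log unit are merged to their geometric mean (the
    lexicographically smallest ID survives); discordant replicate sets are
    dropped entirely.  Output is sorted by molecule_id.

    Raises :class:`CurationError` naming the dominant removal reason if
    nothing survives.
    """
    for col in (id_column, smiles_column, ic50_column):
        if col not in raw.columns:
            raise CurationError(f"raw table lacks required column {col!r}")

    log = CurationLog()
    keep: list[dict] = []
    for _, row in raw.iterrows():
        mid = str(row[id_column])
        ic50, reason = _parse_ic50(row[ic50_column])
        if reason is not None:
            log.add(mid, reason)
            continue
        smi = row[smiles_column]
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) and smi else None
        if mol is None:
            log.add(mid, f"unparseable SMILES: {smi!r}")
            continue
        keep.append(
            {
                "molecule_id": mid,
                "canonical": Chem.MolToSmiles(mol),
                "ic50": ic50,
                "family": row.get(family_column) if family_column in raw.columns else None,
            }
        )

    # deduplicate on canonical structure
    by_structure: dict[str, list[dict]] = {}
    for entry in keep:
        by_structure.setdefault(entry["canonical"], []).append(entry)

    records: list[CompoundRecord] = []
    for canonical, group in by_structure.items():
        group = sorted(group, key=lambda e: e["molecule_id"])
        survivor = group[0]
        values = [e["ic50"] for e in group]
        if len(group) > 1:
            if max(values) / min(values) > 10.0:
                for e in group:
                    log.add(e["molecule_id"],
                            f"discordant replicates (>1 log unit): {canonical}")
                continue
            for e in group[1:]:
                log.add(e["molecule_id"], f"duplicate structure of {survivor['molecule_id']}")
        ic50 = float(np.exp(np.mean(np.log(values))))  # geometric mean
        pic50 = ic50_to_pic50(ic50)
        records.append(
            CompoundRecord(
                molecule_id=survivor["molecule_id"],
                smiles=canonical,
                ic50=ic50,
                pic50=pic50,
                activity_class=assign_class(pic50, cutoff),
                family_label=survivor["family"],
            )
        )

    if not records:
        counts = log.counts()
        dominant = max(counts, key=counts.get) if counts else "empty input"
        raise CurationError(
            f"no compounds survived curation; dominant removal reason: {dominant}"
        )
    records.sort(key=lambda r: r.molecule_id)
    return records, log


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "smiles": [r.smiles for r in records],
            "ic50_nM": [r.ic50 for r in records],
            "pic50": [r.pic50 for r in records],
            "activity_class": [r.activity_class for r in records],
            "family": [r.family_label for r in records],
        }
    )
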