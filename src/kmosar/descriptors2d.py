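"""Bulk 2D descriptor computation for classifier features.

The classifier consumes a wide block of topological/constitutional
descriptors and lets pretreatment and two-stage selection decide which
handful survive; columns are treated as opaque named features.  RDKit's full
2D descriptor list is the source.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors


def compute_descriptor_block(records) -> pd.DataFrame:
    """All RDKit 2D descriptors, one row per compound, indexed by id."""
    rows, index = [], []
    for rec in records:
        mid = getattr(rec, "molecule_id", None) or rec["molecule_id"]
        smi = getattr(rec, "smiles", None) or rec["smiles"]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        rows.append(Descriptors.CalcMolDescriptors(mol))
        index.append(mid)
    df = pd.DataFrame(rows, index=pd.Index(index, name="molecule_id"))
    return df.replace([np.inf, -np.inf], np.nan)
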