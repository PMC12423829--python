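"""Chemical space networks (CSNs).

Compounds are nodes; an edge joins two compounds when the Tanimoto
coefficient of their path-based topological fingerprints reaches the edge
threshold (default 0.68).  Edges are tiered by similarity — thick (Tc >=
0.9), medium (0.7 < Tc < 0.9), thin (Tc <= 0.7) — connected components are
enumerated by size, and communities within the graph are found by greedy
modularity maximisation.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "tanimoto",
    "topological_fingerprints",
    "build_csn",
    "connected_subgraphs",
    "tier_statistics",
    "edge_tier",
    "EDGE_THRESHOLD",
]

EDGE_THRESHOLD = 0.68


def topological_fingerprints(smiles_list, fp_size: int = 2048):
    """RDKit path-based topological fingerprints (the CSN similarity basis)."""
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=fp_size)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def _onbits(fp) -> frozenset:
    if hasattr(fp, "GetOnBits"):
        return frozenset(fp.GetOnBits())
    return frozenset(fp)


def tanimoto(fp_a, fp_b) -> float:
    """|a ∩ b| / |a ∪ b| over fingerprint on-bits.

    Accepts RDKit bit vectors or plain bit-index sets.  Two empty
    fingerprints return 0.0 with a warning (the ratio is formally 0/0).
    """
    if hasattr(fp_a, "GetNumBits") and hasattr(fp_b, "GetNumBits"):
        if fp_a.GetNumBits() != fp_b.GetNumBits():
            raise ValueError(
                f"mismatched fingerprint lengths: {fp_a.GetNumBits()} vs {fp_b.GetNumBits()}"
            )
    elif hasattr(fp_a, "GetNumBits") != hasattr(fp_b, "GetNumBits"):
        raise ValueError("mismatched fingerprint types")
    a, b = _onbits(fp_a), _onbits(fp_b)
    union = len(a | b)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    return len(a & b) / union


def edge_tier(tc: float) -> str:
    """Similarity tier: thick (>=0.9), medium (0.7<tc<0.9), thin (<=0.7).

    Edges at exactly Tc = 0.7 fall in the thin tier.
    """
    if tc >= 0.9:
        return "thick"
    if tc > 0.7:
        return "medium"
    return "thin"


def build_csn(records, fingerprints=None, edge_threshold: float = EDGE_THRESHOLD) -> nx.Graph:
    """Build the thresholded similarity graph over all records.

    Node attributes: pIC50, family, component (index in size order),
    community (greedy modularity within the whole graph).  Edge attributes:
    tc, tier.  Isolated nodes are kept.
    """
    if fingerprints is None:
        fingerprints = topological_fingerprints([r.smiles for r in records])
    ids = [r.molecule_id for r in records]
    g = nx.Graph()
    for r in records:
        g.add_node(r.molecule_id, pic50=float(r.pic50),
                   family=getattr(r, "family_label", None))
    for i in range(len(ids)):
        sims = DataStructs.BulkTanimotoSimilarity(fingerprints[i], fingerprints[i + 1:])
        for k, tc in enumerate(sims):
            j = i + 1 + k
            if tc >= edge_threshold:
                g.add_edge(ids[i], ids[j], tc=float(tc), tier=edge_tier(float(tc)))

    components = sorted(nx.connected_components(g), key=len, reverse=True)
    for ci, comp in enumerate(components):
        for node in comp:
            g.nodes[node]["component"] = ci
    communities = nx.community.greedy_modularity_communities(g)
    for li, comm in enumerate(communities):
        for node in comm:
            g.nodes[node]["community"] = li
    return g


def connected_subgraphs(g: nx.Graph) -> list[nx.Graph]:
    """Connected components as subgraphs, largest first."""
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    return [g.subgraph(c).copy() for c in comps]


def tier_statistics(subgraph: nx.Graph) -> pd.DataFrame:
    """Edge counts and percentages per similarity tier (2 d.p.)."""
    if subgraph.number_of_nodes() < 2 or subgraph.number_of_edges() == 0:
        return pd.DataFrame(columns=["tier", "pairs", "percent"])
    counts = {"thick": 0, "medium": 0, "thin": 0}
    for _, _, data in subgraph.edges(data=True):
        counts[data["tier"]] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "tier": list(counts.keys()),
            "pairs": list(counts.values()),
            "percent": [round(100.0 * c / total, 2) for c in counts.values()],
        }
    )


def export_csn(g: nx.Graph, prefix: str, layout_seed: int = 0) -> None:
    """Write edge list, node table (with spring-layout coordinates) and
    GraphML next to ``prefix``."""
    edges = pd.DataFrame(
        [(i, j, d["tc"], d["tier"]) for i, j, d in g.edges(data=True)],
        columns=["i", "j", "tc", "tier"],
    )
    edges.to_csv(f"{prefix}_edges.csv", index=False)
    pos = nx.spring_layout(g, seed=layout_seed)
    nodes = pd.DataFrame(
        [
            {
                "molecule_id": n,
                "pic50": d.get("pic50", np.nan),
                "component": d.get("component", -1),
                "community": d.get("community", -1),
                "x": pos[n][0],
                "y": pos[n][1],
            }
            for n, d in g.nodes(data=True)
        ]
    )
    nodes.to_csv(f"{prefix}_nodes.csv", index=False)
    clean = g.copy()
    for _, d in clean.nodes(data=True):  # GraphML rejects None attributes
        for k in [k for k, v in d.items() if v is None]:
            del d[k]
    nx.write_graphml(clean, f"{prefix}.graphml")
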