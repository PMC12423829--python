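"""Synthetic congeneric-series generators for pipeline development and testing.

Real KMO-inhibitor activity tables come from bioassay databases and carry the
usual pathologies: replicate measurements, censored ("ranged") IC50 values,
missing entries.  This module fabricates tables with the same statistical
structure — several structurally coherent scaffold families, one large
congeneric series, and a pIC50 that is a planted linear function of
substituent effects plus Gaussian noise — so that curation, network analysis
and field-QSAR parameter recovery can all be exercised with a known ground
truth.  It also provides small hard-coded geometries whose grid interaction
energies have closed-form values, used as oracles for the field engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "PlantedSARSpec",
    "SyntheticActivityData",
    "ToyGeometry",
    "generate_activity_table",
    "generate_toy_geometry",
    "DEFAULT_SCAFFOLDS",
    "DEFAULT_SUBSTITUENTS",
]


class FragmentChemistryError(ValueError):
    """A scaffold/substituent combination produced an unparseable structure."""


# Scaffold templates.  Attachment points are written as "([*:k])" so a
# substituent SMILES can be spliced in textually; hydrogen means the whole
# "([*:k])" group is deleted.  The five parents are deliberately dissimilar
# ring systems so that path-fingerprint similarity separates families.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    # pyrimidine-phenyl, the congeneric series parent
    "c1nc(-c2ccc([*:1])c([*:2])c2)ncc1([*:3])",
    # benzothiazole
    "c1ccc2sc(N([*:1])C(=O)C([*:2]))nc2c1",
    # quinoline carboxamide
    "c1cc2cccnc2c(C(=O)N([*:1])([*:2]))c1",
    # furan-sulfonamide
    "c1cc(S(=O)(=O)N([*:1])([*:2]))co1",
    # indole acetic
    "c1ccc2c(c1)c(CC(=O)O([*:1]))c([*:2])[nH]2",
)

# Substituent vocabulary mirroring common medicinal-chemistry decorations:
# halogens, methyl, methoxy, trifluoromethyl, carboxyl, and unsubstituted.
DEFAULT_SUBSTITUENTS: dict[str, str] = {
    "H": "",
    "F": "F",
    "Cl": "Cl",
    "Me": "C",
    "OMe": "OC",
    "CF3": "C(F)(F)F",
    "COOH": "C(=O)O",
}

# Planted activity increments (pIC50 units) keyed by (position, substituent).
# Position 1 behaves like a "para halogen favourable" site, position 2
# penalises bulk, position 3 rewards the carboxyl.
DEFAULT_EFFECTS: dict[tuple[int, str], float] = {
    (1, "F"): 0.6,
    (1, "Cl"): 0.8,
    (1, "OMe"): -0.5,
    (1, "CF3"): -0.3,
    (2, "Me"): -0.2,
    (2, "CF3"): -0.7,
    (2, "Cl"): 0.3,
    (3, "COOH"): 0.9,
    (3, "OMe"): -0.4,
    (3, "Me"): 0.2,
}


@dataclass(frozen=True)
class PlantedSARSpec:
    """Recipe for a synthetic activity table with a planted SAR.

    pIC50 = baseline + family offset + sum of per-(position, substituent)
    effect coefficients + N(0, noise_sd).  Attachment is positional: each
    scaffold carries numbered attachment points, so "C4'-halogen"-style
    effects are expressible.
    """

    n_compounds: int = 137
    n_families: int = 5
    scaffold_library: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituent_library: tuple[str, ...] = tuple(DEFAULT_SUBSTITUENTS)
    effect_coefficients: dict[tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    baseline: float = 7.3
    family_spread: float = 0.45  # pIC50 step between family baselines
    noise_sd: float = 0.3
    duplicate_fraction: float = 0.05
    missing_fraction: float = 0.05
    ranged_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.n_families < 3:
            raise ValueError("n_families must be >= 3")
        if self.n_families > len(self.scaffold_library):
            raise ValueError(
                f"n_families={self.n_families} exceeds scaffold library size "
                f"{len(self.scaffold_library)}"
            )
        if not self.scaffold_library or not self.substituent_library:
            raise ValueError("scaffold and substituent libraries must be non-empty")


@dataclass
class SyntheticActivityData:
    """Generated table plus the hidden truth needed by recovery tests."""

    table: pd.DataFrame          # raw rows incl. injected duplicates/missing
    clean: pd.DataFrame          # one row per unique compound, no injections
    design: pd.DataFrame         # substituent indicator matrix (clean rows)
    effects: dict[tuple[int, str], float]
    spec: PlantedSARSpec

    def write_csv(self, path: str) -> None:
        self.table[["molecule_id", "smiles", "ic50_nM"]].to_csv(path, index=False)


def _n_attachment_points(template: str) -> int:
    k = 1
    while f"[*:{k}]" in template:
        k += 1
    return k - 1


def _instantiate(template: str, choices: dict[int, str],
                 substituents: dict[str, str]) -> str:
    """Splice substituent fragments into a scaffold template."""
    smi = template
    for pos, name in choices.items():
        frag = substituents[name]
        placeholder = f"([*:{pos}])"
        smi = smi.replace(placeholder, f"({frag})" if frag else "")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise FragmentChemistryError(
            f"invalid fragment chemistry: template {template!r} with "
            f"{choices!r} gave unparseable SMILES {smi!r}"
        )
    return Chem.MolToSmiles(mol)


def _family_sizes(n: int, n_families: int) -> list[int]:
    """Even split, but force family 0 to hold a congeneric series of >=20
    members whenever n allows."""
    base = [n // n_families] * n_families
    for i in range(n % n_families):
        base[i] += 1
    want = min(20, max(1, n - (n_families - 1)))
    while base[0] < want:
        donor = int(np.argmax(base[1:])) + 1
        if base[donor] <= 1:
            break
        base[donor] -= 1
        base[0] += 1
    return base


def generate_activity_table(spec: PlantedSARSpec) -> SyntheticActivityData:
    """Generate a ChEMBL-style activity table with a planted linear SAR.

    Deterministic for a fixed ``spec.seed``.  IC50 is reported in nM,
    back-computed as ``10**(9 - pIC50)``.  A ``duplicate_fraction`` of rows is
    re-emitted under fresh IDs and a ``missing_fraction`` of extra rows lack
    IC50 values, so downstream curation has real work to do.
    """
    rng = np.random.default_rng(spec.seed)
    substituents = {k: DEFAULT_SUBSTITUENTS[k] for k in spec.substituent_library}
    sizes = _family_sizes(spec.n_compounds, spec.n_families)

    rows: list[dict] = []
    design_rows: list[dict] = []
    seen: set[str] = set()
    idx = 0
    for fam, size in enumerate(sizes):
        template = spec.scaffold_library[fam]
        npos = _n_attachment_points(template)
        fam_offset = (fam - (spec.n_families - 1) / 2.0) * spec.family_spread
        made = 0
        attempts = 0
        max_attempts = 200 * size
        while made < size and attempts < max_attempts:
            attempts += 1
            choices = {
                pos: spec.substituent_library[rng.integers(len(spec.substituent_library))]
                for pos in range(1, npos + 1)
            }
            smiles = _instantiate(template, choices, substituents)
            if smiles in seen:
                continue
            seen.add(smiles)
            effect = sum(
                spec.effect_coefficients.get((pos, name), 0.0)
                for pos, name in choices.items()
            )
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            pic50 = spec.baseline + fam_offset + effect + noise
            pic50 = float(np.clip(pic50, 3.0, 11.0))
            idx += 1
            mol_id = f"K{idx:03d}"
            rows.append(
                {
                    "molecule_id": mol_id,
                    "smiles": smiles,
                    "ic50_nM": 10.0 ** (9.0 - pic50),
                    "family": f"F{fam}",
                    "true_pic50": pic50,
                }
            )
            ind = {"molecule_id": mol_id}
            for key in spec.effect_coefficients:
                pos, name = key
                ind[f"pos{pos}_{name}"] = int(choices.get(pos) == name)
            design_rows.append(ind)
            made += 1
        if made < size:
            raise FragmentChemistryError(
                f"could not generate {size} unique members for family {fam} "
                f"(template {template!r}); combination space too small"
            )

    clean = pd.DataFrame(rows)
    design = pd.DataFrame(design_rows).set_index("molecule_id")

    # Inject curation work: structural duplicates under new IDs, then rows
    # with missing (and optionally range-censored) IC50 values.
    n = len(clean)
    n_dup = int(round(spec.duplicate_fraction * n))
    n_miss = int(round(spec.missing_fraction * n))
    n_rng = int(round(spec.ranged_fraction * n))
    raw = [clean[["molecule_id", "smiles", "ic50_nM", "family"]]]
    if n_dup:
        picks = rng.choice(n, size=n_dup, replace=False)
        dup = clean.iloc[picks][["smiles", "ic50_nM", "family"]].copy()
        dup.insert(0, "molecule_id", [f"XDUP{j:03d}" for j in range(n_dup)])
        raw.append(dup)
    if n_miss:
        picks = rng.choice(n, size=n_miss, replace=False)
        miss = clean.iloc[picks][["family"]].copy()
        miss.insert(0, "molecule_id", [f"XMIS{j:03d}" for j in range(n_miss)])
        # new scaffolds are not needed; reuse structures but blank the assay
        miss.insert(1, "smiles", clean.iloc[picks]["smiles"].values)
        miss.insert(2, "ic50_nM", np.nan)
        raw.append(miss)
    if n_rng:
        picks = rng.choice(n, size=n_rng, replace=False)
        rngd = clean.iloc[picks][["family"]].copy()
        rngd.insert(0, "molecule_id", [f"XRNG{j:03d}" for j in range(n_rng)])
        rngd.insert(1, "smiles", clean.iloc[picks]["smiles"].values)
        rngd.insert(2, "ic50_nM", ">10000")
        raw.append(rngd)
    table = pd.concat(raw, ignore_index=True)

    return SyntheticActivityData(
        table=table, clean=clean, design=design,
        effects=dict(spec.effect_coefficients), spec=spec,
    )


# --------------------------------------------------------------------------
# Toy geometries: closed-form oracles for the grid-energy engine.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyGeometry:
    """Hard-coded atoms with charges and LJ parameters for energy oracles."""

    name: str
    atom_elements: tuple[str, ...]
    coordinates: np.ndarray        # (n, 3) Å
    partial_charges: np.ndarray    # elementary charges
    lj_epsilon: np.ndarray         # kcal/mol
    lj_sigma: np.ndarray           # Å

    def __post_init__(self) -> None:
        n = len(self.atom_elements)
        if not (len(self.coordinates) == len(self.partial_charges)
                == len(self.lj_epsilon) == len(self.lj_sigma) == n):
            raise ValueError("per-atom arrays must share one length")


def _toy(name, elements, coords, q, eps, sig) -> ToyGeometry:
    return ToyGeometry(
        name=name,
        atom_elements=tuple(elements),
        coordinates=np.asarray(coords, dtype=float),
        partial_charges=np.asarray(q, dtype=float),
        lj_epsilon=np.asarray(eps, dtype=float),
        lj_sigma=np.asarray(sig, dtype=float),
    )


def generate_toy_geometry(name: str) -> ToyGeometry:
    """Return one of the named fixtures: diatomic, water_like, benzene_like."""
    if name == "diatomic":
        return _toy(
            "diatomic", ["C", "C"],
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
            [0.5, -0.5], [0.1, 0.1], [3.4, 3.4],
        )
    if name == "water_like":
        # bent triatomic, 0.9572 Å bonds, 104.52° angle, net charge 0
        ang = math.radians(104.52 / 2.0)
        r = 0.9572
        return _toy(
            "water_like", ["O", "H", "H"],
            [[0.0, 0.0, 0.0],
             [r * math.sin(ang), r * math.cos(ang), 0.0],
             [-r * math.sin(ang), r * math.cos(ang), 0.0]],
            [-0.834, 0.417, 0.417],
            [0.152, 0.0, 0.0], [3.15, 0.4, 0.4],
        )
    if name == "benzene_like":
        coords, elements, q, eps, sig = [], [], [], [], []
        for k in range(6):
            th = math.pi * k / 3.0
            coords.append([1.39 * math.cos(th), 1.39 * math.sin(th), 0.0])
            elements.append("C")
            q.append(-0.115)
            eps.append(0.086)
            sig.append(3.4)
        for k in range(6):
            th = math.pi * k / 3.0
            coords.append([2.48 * math.cos(th), 2.48 * math.sin(th), 0.0])
            elements.append("H")
            q.append(0.115)
            eps.append(0.03)
            sig.append(2.5)
        return _toy("benzene_like", elements, coords, q, eps, sig)
    raise ValueError(
        f"unknown toy geometry {name!r}; choose one of: "
        "diatomic, water_like, benzene_like"
    )


def plant_field_response(
    columns: pd.DataFrame,
    n_effects: int = 3,
    effect_sizes: Sequence[float] = (1.0, -0.8, 0.6),
    noise_sd: float = 0.3,
    baseline: float = 7.0,
    max_abs_corr: float = 0.4,
    seed: int = 0,
) -> tuple[pd.Series, dict[object, float]]:
    """Plant a linear activity on real field-descriptor columns.

    Picks ``n_effects`` high-variance, mutually decorrelated columns of the
    (pruned) field matrix and builds ``y = baseline + sum beta_j * z_j +
    N(0, noise_sd)`` with z the standardised column.  Returns the response and
    the planted {column: beta} map, the ground truth for coefficient-sign
    recovery tests.
    """
    rng = np.random.default_rng(seed)
    X = columns.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    order = np.argsort(sd)[::-1]
    chosen: list[int] = []
    for j in order:
        if sd[j] <= 0:
            continue
        ok = all(
            abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) <= max_abs_corr
            for k in chosen
        )
        if ok:
            chosen.append(int(j))
        if len(chosen) == n_effects:
            break
    if len(chosen) < n_effects:
        raise ValueError(
            f"only {len(chosen)} sufficiently decorrelated columns available"
        )
    betas = list(effect_sizes)[:n_effects]
    y = np.full(len(columns), baseline, dtype=float)
    planted: dict[object, float] = {}
    for j, b in zip(chosen, betas):
        z = (X[:, j] - X[:, j].mean()) / sd[j]
        y += b * z
        planted[columns.columns[j]] = float(b)
    y += rng.normal(0.0, noise_sd, size=len(y))
    return pd.Series(y, index=columns.index, name="pic50"), planted
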