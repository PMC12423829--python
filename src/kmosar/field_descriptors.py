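"""Grid-based molecular interaction field descriptors for 3D/4D QSAR.

Each molecule is represented by a conformer ensemble (its conformational
ensemble profile, CEP) aligned to a reference compound.  A probe particle is
placed at every node of a rectangular grid enclosing all aligned structures,
and the probe-molecule Lennard-Jones and Coulomb interaction energies become
the descriptor columns:

    E_LJ = sum_atoms 4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ]
    E_C  = k sum_atoms q_i q_probe / r_i,   k = 332.0636 kcal Å mol^-1 e^-2

with Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon) and
energies clamped to ±truncation to tame the r^-12 singularity.  3D mode uses
a single designated conformer; 4D mode averages each grid energy over the
ensemble.

Conformer generation here is a stochastic distance-geometry ensemble with
force-field refinement and empirical (Gasteiger) charges — a declared
stand-in for the molecular-dynamics ensembles and quantum-chemical charges
used in production field-QSAR workflows; the substitution is recorded in the
matrix metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .synthetic import ToyGeometry

__all__ = [
    "COULOMB_K",
    "ConformerEnsemble",
    "ProbeSpec",
    "EnergyGrid",
    "FieldDescriptorMatrix",
    "embed_and_sample",
    "ensemble_from_geometry",
    "align_to_reference",
    "kabsch",
    "build_grid",
    "probe_energies",
    "field_matrix",
    "prune_columns",
    "write_cube",
    "read_cube",
]

COULOMB_K = 332.0636  # kcal·Å·mol^-1·e^-2

# UFF-style van der Waals parameters per element: (well depth kcal/mol,
# minimum-energy distance Å).  sigma = x_min / 2^(1/6).
_UFF_VDW: dict[str, tuple[float, float]] = {
    "H": (0.044, 2.886),
    "C": (0.105, 3.851),
    "N": (0.069, 3.660),
    "O": (0.060, 3.500),
    "F": (0.050, 3.364),
    "P": (0.305, 4.147),
    "S": (0.274, 4.035),
    "Cl": (0.227, 3.947),
    "Br": (0.251, 4.189),
    "I": (0.339, 4.50),
}
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ProbeSpec:
    """Probe particle: sp3-carbon-like site with unit positive charge."""

    charge: float = 1.0           # e
    lj_epsilon: float = 0.1094    # kcal/mol
    lj_sigma: float = 3.4         # Å
    truncation: float = 30.0      # kcal/mol cap on |energy|

    def __post_init__(self) -> None:
        if not self.truncation > 0:
            raise ValueError("truncation must be positive")


@dataclass
class ConformerEnsemble:
    """Aligned conformations of one molecule with per-atom parameters."""

    molecule_id: str
    conformers: np.ndarray        # (n_conf, n_atoms, 3) Å
    partial_charges: np.ndarray   # (n_atoms,) e
    lj_epsilon: np.ndarray        # (n_atoms,) kcal/mol
    lj_sigma: np.ndarray          # (n_atoms,) Å
    elements: tuple[str, ...] = ()
    reference_id: str | None = None   # alignment reference, None if unaligned
    formal_charge: float = 0.0

    def __post_init__(self) -> None:
        self.conformers = np.asarray(self.conformers, dtype=float)
        if self.conformers.ndim != 3 or self.conformers.shape[2] != 3:
            raise ValueError("conformers must have shape (n_conf, n_atoms, 3)")
        n_atoms = self.conformers.shape[1]
        for name in ("partial_charges", "lj_epsilon", "lj_sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        if abs(self.partial_charges.sum() - self.formal_charge) > 1e-6:
            raise ValueError(
                f"charges sum to {self.partial_charges.sum():.6f}, expected "
                f"formal charge {self.formal_charge}"
            )

    @property
    def n_conformers(self) -> int:
        return self.conformers.shape[0]


class EmbeddingError(RuntimeError):
    pass


def _atom_lj(symbol: str) -> tuple[float, float]:
    eps, xmin = _UFF_VDW.get(symbol, _UFF_VDW["C"])
    return eps, xmin / _SIXTH_ROOT_2


def embed_and_sample(record, n_conformers: int = 10, seed: int = 0) -> ConformerEnsemble:
    """Generate a conformer ensemble for one compound.

    Distance-geometry embedding (ETKDG, seeded), MMFF94 refinement (UFF
    fallback), Gasteiger partial charges normalised to the formal molecular
    charge, and UFF-style LJ parameters per element.  Deterministic for a
    fixed seed.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    mid = getattr(record, "molecule_id", None) or record["molecule_id"]
    smi = getattr(record, "smiles", None) or record["smiles"]
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise EmbeddingError(f"{mid}: unparseable SMILES {smi!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if len(conf_ids) == 0:
        raise EmbeddingError(f"{mid}: distance-geometry embedding failed")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)

    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    q = np.nan_to_num(q)
    formal = float(Chem.GetFormalCharge(mol))
    q += (formal - q.sum()) / len(q)  # renormalise to the formal charge

    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    eps, sig = np.empty(len(elements)), np.empty(len(elements))
    for i, el in enumerate(elements):
        eps[i], sig[i] = _atom_lj(el)

    coords = np.stack([mol.GetConformer(c).GetPositions() for c in conf_ids])
    return ConformerEnsemble(
        molecule_id=mid, conformers=coords, partial_charges=q,
        lj_epsilon=eps, lj_sigma=sig, elements=elements, formal_charge=formal,
    )


def ensemble_from_geometry(geom: ToyGeometry, n_copies: int = 1) -> ConformerEnsemble:
    """Wrap a hard-coded toy geometry as a (repeated) one-molecule ensemble."""
    coords = np.repeat(geom.coordinates[None, :, :], n_copies, axis=0)
    return ConformerEnsemble(
        molecule_id=geom.name, conformers=coords,
        partial_charges=geom.partial_charges, lj_epsilon=geom.lj_epsilon,
        lj_sigma=geom.lj_sigma, elements=geom.atom_elements,
        formal_charge=float(geom.partial_charges.sum()),
    )


def ensemble_to_sdf(ensemble: ConformerEnsemble, smiles: str, path) -> None:
    """Write an ensemble as a multi-record SDF (one record per conformer).

    Atom ordering must match the ensemble's (hydrogens explicit, as produced
    by :func:`embed_and_sample`); partial charges are stored per record in
    the ``partial_charges`` property.
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if mol.GetNumAtoms() != ensemble.conformers.shape[1]:
        raise ValueError(
            f"SMILES atom count {mol.GetNumAtoms()} does not match ensemble "
            f"({ensemble.conformers.shape[1]} atoms)"
        )
    writer = Chem.SDWriter(str(path))
    try:
        for k in range(ensemble.n_conformers):
            conf = Chem.Conformer(mol.GetNumAtoms())
            for a in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(a, ensemble.conformers[k, a].tolist())
            work = Chem.Mol(mol)
            work.RemoveAllConformers()
            work.AddConformer(conf, assignId=True)
            work.SetProp("_Name", ensemble.molecule_id)
            work.SetProp("conformer_index", str(k))
            work.SetProp("partial_charges",
                         ",".join(f"{q:.6f}" for q in ensemble.partial_charges))
            writer.write(work)
    finally:
        writer.close()


def ensemble_from_sdf(path, molecule_id: str | None = None) -> ConformerEnsemble:
    """Read a multi-record SDF (as written by :func:`ensemble_to_sdf`) back
    into a :class:`ConformerEnsemble`; LJ parameters are re-derived from the
    elements."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"no parseable records in {path}")
    if molecule_id is None:
        molecule_id = mols[0].GetProp("_Name") if mols[0].HasProp("_Name") else "mol"
    coords = np.stack([m.GetConformer().GetPositions() for m in mols])
    if mols[0].HasProp("partial_charges"):
        q = np.array([float(x) for x in
                      mols[0].GetProp("partial_charges").split(",")])
    else:
        q = np.zeros(mols[0].GetNumAtoms())
    elements = tuple(a.GetSymbol() for a in mols[0].GetAtoms())
    eps, sig = np.empty(len(elements)), np.empty(len(elements))
    for i, el in enumerate(elements):
        eps[i], sig[i] = _atom_lj(el)
    return ConformerEnsemble(
        molecule_id=molecule_id, conformers=coords, partial_charges=q,
        lj_epsilon=eps, lj_sigma=sig, elements=elements,
        formal_charge=float(q.sum()),
    )


# --------------------------------------------------------------------------
# Rigid alignment
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with
    ``mobile @ R.T + t ≈ target`` (proper rotation, no reflection)."""
    mc, tc = mobile.mean(0), target.mean(0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def align_to_reference(
    ensemble: ConformerEnsemble,
    reference_conformer: np.ndarray,
    atom_map: list[tuple[int, int]],
    reference_id: str = "reference",
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Superpose every conformer onto the reference over mapped atom pairs.

    ``atom_map`` pairs (ensemble_atom, reference_atom); at least three
    non-collinear reference atoms are required.  Returns the aligned ensemble
    and the per-conformer RMSD over the mapped atoms.
    """
    if len(atom_map) < 3:
        raise ValueError("atom_map needs at least 3 atom pairs")
    ref = np.asarray(reference_conformer, dtype=float)
    mob_idx = [a for a, _ in atom_map]
    ref_idx = [b for _, b in atom_map]
    ref_sel = ref[ref_idx]
    centered = ref_sel - ref_sel.mean(0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("mapped reference atoms are collinear or degenerate")

    aligned = np.empty_like(ensemble.conformers)
    rmsd = np.empty(ensemble.n_conformers)
    for k in range(ensemble.n_conformers):
        conf = ensemble.conformers[k]
        R, t = kabsch(conf[mob_idx], ref_sel)
        moved = conf @ R.T + t
        aligned[k] = moved
        delta = moved[mob_idx] - ref_sel
        rmsd[k] = math.sqrt((delta ** 2).sum() / len(atom_map))
    out = replace(ensemble)
    out.conformers = aligned
    out.reference_id = reference_id
    return out, rmsd


# --------------------------------------------------------------------------
# Grid and energies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyGrid:
    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid nodes as an (n_points, 3) array, x fastest-varying last."""
        axes = [
            self.origin[d] + self.spacing * np.arange(self.dims[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_grid(ensembles, spacing: float = 1.0, margin: float = 4.0) -> EnergyGrid:
    """Axis-aligned box covering every atom of every ensemble plus margin."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if spacing <= 0 or margin <= 0:
        raise ValueError("spacing and margin must be positive")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for ens in ensembles:
        pts = ens.conformers.reshape(-1, 3)
        lo = np.minimum(lo, pts.min(0))
        hi = np.maximum(hi, pts.max(0))
    lo -= margin
    hi += margin
    dims = tuple(int(math.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return EnergyGrid(origin=tuple(lo), spacing=spacing, dims=dims)


def probe_energies(
    coords: np.ndarray,
    charges: np.ndarray,
    lj_epsilon: np.ndarray,
    lj_sigma: np.ndarray,
    points: np.ndarray,
    probe: ProbeSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """(E_LJ, E_C) in kcal/mol at each probe point for one conformer.

    Lorentz-Berthelot combination; each summed energy clamped to
    ±probe.truncation.  Grid points landing on an atom (r < 1e-6 Å) receive
    the clamped value.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)  # coincident-point guard; energy will clamp
    sig_ij = 0.5 * (lj_sigma + probe.lj_sigma)[None, :]
    eps_ij = np.sqrt(lj_epsilon * probe.lj_epsilon)[None, :]
    sr6 = (sig_ij / d) ** 6
    e_lj = (4.0 * eps_ij * (sr6 ** 2 - sr6)).sum(axis=1)
    e_c = COULOMB_K * probe.charge * (charges[None, :] / d).sum(axis=1)
    cap = probe.truncation
    return np.clip(e_lj, -cap, cap), np.clip(e_c, -cap, cap)


@dataclass
class FieldDescriptorMatrix:
    values: pd.DataFrame          # rows: molecule ids; columns: (grid_idx, type)
    grid: EnergyGrid
    probe: ProbeSpec
    mode: str                     # "3D" | "4D"
    metadata: dict = field(default_factory=dict)

    def energy_type_columns(self, energy_type: str):
        return [c for c in self.values.columns if c[1] == energy_type]


def field_matrix(
    ensembles,
    grid: EnergyGrid,
    probe: ProbeSpec | None = None,
    mode: str = "4D",
) -> FieldDescriptorMatrix:
    """Molecules × (grid point, energy type) interaction-energy matrix.

    3D mode evaluates the first (designated) conformer only; 4D mode is the
    arithmetic mean of the per-conformer energies over the CEP.  All
    ensembles must be aligned to the same reference.
    """
    if mode not in ("3D", "4D"):
        raise ValueError("mode must be '3D' or '4D'")
    probe = probe or ProbeSpec()
    refs = {e.reference_id for e in ensembles}
    if len(refs) > 1:
        raise ValueError(f"mixed alignment references: {sorted(map(str, refs))}")
    pts = grid.points()
    rows, ids = [], []
    for ens in ensembles:
        confs = ens.conformers[:1] if mode == "3D" else ens.conformers
        lj_acc = np.zeros(grid.n_points)
        c_acc = np.zeros(grid.n_points)
        for conf in confs:
            e_lj, e_c = probe_energies(
                conf, ens.partial_charges, ens.lj_epsilon, ens.lj_sigma, pts, probe
            )
            lj_acc += e_lj
            c_acc += e_c
        k = len(confs)
        rows.append(np.concatenate([lj_acc / k, c_acc / k]))
        ids.append(ens.molecule_id)
    columns = pd.MultiIndex.from_tuples(
        [(i, "LJ") for i in range(grid.n_points)]
        + [(i, "C") for i in range(grid.n_points)],
        names=["grid_idx", "energy_type"],
    )
    values = pd.DataFrame(rows, index=ids, columns=columns)
    meta = {
        "coulomb_constant": COULOMB_K,
        "probe": probe,
        "truncation_kcal_mol": probe.truncation,
        "charge_model": "Gasteiger (empirical); stand-in for quantum-chemical charges",
        "ensemble_model": "distance-geometry + force-field refinement; stand-in for MD CEP",
        "units": "kcal/mol, Å",
    }
    return FieldDescriptorMatrix(values=values, grid=grid, probe=probe,
                                 mode=mode, metadata=meta)


class PruningError(ValueError):
    pass


def prune_columns(
    matrix: FieldDescriptorMatrix | pd.DataFrame,
    variance_floor: float = 1e-4,
    correlation_ceiling: float = 0.99,
    y=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Standard field-matrix pretreatment.

    Columns with variance below ``variance_floor`` are dropped.  Within
    groups of mutually correlated columns (|r| above ``correlation_ceiling``)
    only one survives: the member most correlated with the response when
    ``y`` is given, otherwise the highest-variance member.  Returns the
    reduced frame and a removal trace.
    """
    df = matrix.values if isinstance(matrix, FieldDescriptorMatrix) else matrix
    X = df.to_numpy(dtype=float)
    var = X.var(axis=0, ddof=0)
    trace: list[dict] = []
    alive = var >= variance_floor
    trace.append({
        "stage": "variance",
        "removed": int((~alive).sum()),
        "floor": variance_floor,
    })
    idx_alive = np.flatnonzero(alive)
    if idx_alive.size == 0:
        raise PruningError(
            f"all columns pruned (variance floor {variance_floor}, "
            f"correlation ceiling {correlation_ceiling})"
        )

    if y is not None:
        yv = np.asarray(y, dtype=float)
        yc = yv - yv.mean()
        score = np.zeros(X.shape[1])
        for j in idx_alive:
            xc = X[:, j] - X[:, j].mean()
            denom = math.sqrt((xc * xc).sum() * (yc * yc).sum())
            score[j] = abs((xc * yc).sum() / denom) if denom > 0 else 0.0
    else:
        score = var

    order = sorted(idx_alive, key=lambda j: (-score[j], j))
    kept: list[int] = []
    Xc = X - X.mean(0)
    norms = np.sqrt((Xc ** 2).sum(0))
    dropped_corr = 0
    for j in order:
        redundant = False
        for k in kept:
            denom = norms[j] * norms[k]
            r = abs((Xc[:, j] * Xc[:, k]).sum() / denom) if denom > 0 else 0.0
            if r > correlation_ceiling:
                redundant = True
                break
        if redundant:
            dropped_corr += 1
        else:
            kept.append(j)
    trace.append({
        "stage": "correlation",
        "removed": dropped_corr,
        "ceiling": correlation_ceiling,
    })
    kept_sorted = sorted(kept)
    return df.iloc[:, kept_sorted], trace


# --------------------------------------------------------------------------
# Gaussian cube export (Å -> Bohr)
# --------------------------------------------------------------------------

_BOHR = 0.529177210903  # Å


def write_cube(path, grid: EnergyGrid, values: np.ndarray, comment: str = "field") -> None:
    """Write a scalar grid field as a Gaussian cube file (no atoms block)."""
    v = np.asarray(values, dtype=float).reshape(grid.dims)
    nx, ny, nz = grid.dims
    ox, oy, oz = (c / _BOHR for c in grid.origin)
    s = grid.spacing / _BOHR
    with open(path, "w") as fh:
        fh.write(f"{comment}\nscalar field, kcal/mol\n")
        fh.write(f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        fh.write(f"{nx:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{ny:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}\n")
        fh.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        flat = v.ravel()
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write("".join(f"{x:13.5E}" for x in chunk) + "\n")


def read_cube(path) -> tuple[EnergyGrid, np.ndarray]:
    """Read back a cube file written by :func:`write_cube`."""
    with open(path) as fh:
        lines = fh.readlines()
    natoms = int(lines[2].split()[0])
    origin = tuple(float(x) * _BOHR for x in lines[2].split()[1:4])
    dims, spacing = [], None
    for d in range(3):
        parts = lines[3 + d].split()
        dims.append(int(parts[0]))
        step = float(parts[1 + d]) * _BOHR
        spacing = step if spacing is None else spacing
    data = []
    for line in lines[6 + natoms:]:
        data.extend(float(x) for x in line.split())
    grid = EnergyGrid(origin=origin, spacing=spacing, dims=tuple(dims))
    return grid, np.array(data).reshape(grid.dims)
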