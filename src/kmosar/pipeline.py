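"""End-to-end study recipe: curation through field QSAR, with provenance.

``run_pipeline`` executes the nine stages in dependency order — curate,
physchem, split, classify, ad, csn, conformers, fields, pls — writing each
stage's artifacts into its own subdirectory of the run directory and a
manifest recording package versions, seeds and a SHA-256 hash of every file.
Stages communicate only through their declared files; rerunning with the
same configuration reproduces the hashes of all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity_model import (
    evaluate,
    pretreat,
    select_features,
    split_and_map,
    train_classifier,
)
from .applicability_domain import ad_report, leverage
from .csn import build_csn, connected_subgraphs, export_csn, tier_statistics
from .curation import CompoundRecord, curate, records_to_frame
from .descriptors2d import compute_descriptor_block
from .field_descriptors import (
    ProbeSpec,
    align_to_reference,
    build_grid,
    embed_and_sample,
    field_matrix,
    prune_columns,
    write_cube,
)
from .physchem import compute_physchem, correlation_matrix, summarize
from .pls import (
    choose_n_lv,
    coefficient_map,
    fit_pls,
    select_variables,
    summarize_model,
    y_randomization,
)
from .synthetic import PlantedSARSpec, generate_activity_table

STAGES = (
    "curate", "physchem", "split", "classify", "ad", "csn",
    "conformers", "fields", "pls",
)


@dataclass
class RunConfig:
    """Flat, serialisable run configuration.

    Defaults follow the study conventions throughout: potency cutoff 7.6
    pIC50, CSN edge threshold Tc 0.68, 28 test compounds, 5 k-means
    clusters, PDP/importance settings per the classifier module.
    """

    input_csv: str | None = None        # raw activity table; None -> synthetic
    out_dir: str = "run"
    cutoff: float = 7.6
    edge_threshold: float = 0.68
    n_test: int = 28
    k_clusters: int = 5
    n_trials: int = 30
    cv_folds: int = 5
    top_k_features: int = 8
    # seeds, per stage
    seed_synth: int = 0
    seed_split: int = 42
    seed_train: int = 0
    seed_layout: int = 0
    seed_conformers: int = 0
    # synthetic generation
    synth_n_compounds: int = 137
    synth_n_families: int = 5
    synth_noise_sd: float = 0.3
    # field settings
    n_conformers: int = 5
    grid_spacing: float = 1.0
    grid_margin: float = 4.0
    probe_charge: float = 1.0
    probe_epsilon: float = 0.1094
    probe_sigma: float = 3.4
    truncation: float = 30.0
    field_mode: str = "4D"
    variance_floor: float = 1e-4
    correlation_ceiling: float = 0.99
    max_lv: int = 10
    max_field_features: int = 12
    stages: tuple[str, ...] = STAGES

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, log_tail: str):
        super().__init__(f"stage {stage!r} failed:\n{log_tail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package_version": __version__,
        "stages": {},
        "seeds": {
            "synth": config.seed_synth, "split": config.seed_split,
            "train": config.seed_train, "conformers": config.seed_conformers,
        },
    }
    try:
        import rdkit
        manifest["rdkit_version"] = rdkit.__version__
    except Exception:
        pass

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, state, stage_dir)
        except Exception as err:  # halt with the stage name and its log tail
            raise StageFailure(stage, f"{type(err).__name__}: {err}") from err
        files = sorted(p for p in stage_dir.rglob("*") if p.is_file())
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_curate(cfg: RunConfig, state: dict, d: Path) -> None:
    if cfg.input_csv is not None:
        raw = pd.read_csv(cfg.input_csv, dtype={"ic50_nM": object})
    else:
        spec = PlantedSARSpec(
            n_compounds=cfg.synth_n_compounds, n_families=cfg.synth_n_families,
            noise_sd=cfg.synth_noise_sd, seed=cfg.seed_synth,
        )
        data = generate_activity_table(spec)
        data.write_csv(d / "synthetic_raw.csv")
        raw = data.table
    records, log = curate(raw, cutoff=cfg.cutoff)
    state["records"] = records
    records_to_frame(records).to_csv(d / "curated.csv", index=False)
    (d / "curation_log.txt").write_text(log.to_text())


def _stage_physchem(cfg: RunConfig, state: dict, d: Path) -> None:
    records = state["records"]
    table = compute_physchem(records)
    table.to_csv(d / "physchem.csv")
    pic50 = pd.Series([r.pic50 for r in records], index=table.index)
    cls = pd.Series([r.activity_class for r in records], index=table.index)
    corr = correlation_matrix(table, pic50)
    corr.to_csv(d / "correlation.csv")
    summary = summarize(table, cls)
    summary.stats.to_csv(d / "summary.csv")
    state["physchem"] = table


def _stage_split(cfg: RunConfig, state: dict, d: Path) -> None:
    records = state["records"]
    sm = split_and_map(records, n_test=cfg.n_test, k_clusters=cfg.k_clusters,
                       seed=cfg.seed_split)
    state["split"] = sm
    pd.DataFrame({
        "molecule_id": [r.molecule_id for r in records],
        "set": ["test" if r.molecule_id in set(sm.test_ids) else "train"
                 for r in records],
    }).to_csv(d / "assignment.csv", index=False)
    sm.embedding.join(sm.cluster_labels).to_csv(d / "embedding.csv")


def _stage_classify(cfg: RunConfig, state: dict, d: Path) -> None:
    records = state["records"]
    sm = state["split"]
    block = compute_descriptor_block(records)
    y = pd.Series({r.molecule_id: r.activity_class for r in records})
    train_ids = [i for i in block.index if i in set(sm.train_ids)]
    test_ids = [i for i in block.index if i in set(sm.test_ids)]

    pretreated = pretreat(block.loc[train_ids])
    selected = select_features(
        pretreated, y.loc[train_ids], top_k=cfg.top_k_features, seed=cfg.seed_train
    )
    feats = selected.feature_names
    model, report = train_classifier(
        selected.values.to_numpy(float), y.loc[train_ids],
        n_trials=cfg.n_trials, cv_folds=cfg.cv_folds, seed=cfg.seed_train,
    )
    test_report = evaluate(model, block.loc[test_ids, feats].to_numpy(float),
                           y.loc[test_ids])
    payload = {
        "features": feats,
        "hyperparameters": report.hyperparameters,
        "cv_mean_accuracy": report.cv_mean_accuracy,
        "train": {"accuracy": report.accuracy, "precision": report.precision,
                  "recall": report.recall, "f1": report.f1, "auc": report.auc,
                  "confusion": report.confusion},
        "test": {"accuracy": test_report.accuracy, "precision": test_report.precision,
                 "recall": test_report.recall, "f1": test_report.f1,
                 "auc": test_report.auc, "confusion": test_report.confusion},
        "selection_trace_stages": [t["stage"] for t in selected.selection_trace],
    }
    (d / "report.json").write_text(json.dumps(payload, indent=2))
    with open(d / "model.pkl", "wb") as fh:
        pickle.dump({"model": model, "features": feats,
                     "package_version": __version__,
                     "hyperparameters": report.hyperparameters}, fh)
    state["model"] = model
    state["features"] = feats
    state["descriptor_block"] = block
    state["labels"] = y


def _stage_ad(cfg: RunConfig, state: dict, d: Path) -> None:
    sm = state["split"]
    block, feats = state["descriptor_block"], state["features"]
    train = block.loc[[i for i in block.index if i in set(sm.train_ids)], feats]
    test = block.loc[[i for i in block.index if i in set(sm.test_ids)], feats]
    result = leverage(train, test)
    result.to_csv(d / "leverage.csv")
    (d / "ad_report.json").write_text(json.dumps(ad_report(result), indent=2))


def _stage_csn(cfg: RunConfig, state: dict, d: Path) -> None:
    records = state["records"]
    g = build_csn(records, edge_threshold=cfg.edge_threshold)
    export_csn(g, str(d / "csn"), layout_seed=cfg.seed_layout)
    subs = connected_subgraphs(g)
    stats = []
    for i, sub in enumerate(subs):
        t = tier_statistics(sub)
        if len(t):
            t.insert(0, "subgraph", i)
            stats.append(t)
    if stats:
        pd.concat(stats, ignore_index=True).to_csv(d / "tier_statistics.csv", index=False)
    state["csn"] = g


def _congeneric_series(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Largest structural family (by label when present, else the largest
    CSN-free fallback: all records)."""
    families: dict[str, list[CompoundRecord]] = {}
    for r in records:
        families.setdefault(r.family_label or "all", []).append(r)
    return max(families.values(), key=len)


def build_aligned_ensembles(
    series: list[CompoundRecord],
    n_conformers: int,
    seed: int,
) -> tuple[list, list[tuple[str, str]], str]:
    """Conformer ensembles for a congeneric series, superposed on the most
    active member over their maximum common substructure.

    Returns (aligned ensembles, skipped (id, reason) pairs, reference id).
    """
    from rdkit import Chem
    from rdkit.Chem import rdFMCS

    reference = max(series, key=lambda r: r.pic50)  # most active compound
    ref_ens = embed_and_sample(reference, n_conformers=n_conformers, seed=seed)
    ref_conf = ref_ens.conformers[0]
    ref_mol = Chem.AddHs(Chem.MolFromSmiles(reference.smiles))
    ensembles, skipped = [], []
    for rec in series:
        if rec.molecule_id == reference.molecule_id:
            ensembles.append(
                dataclasses.replace(ref_ens, reference_id=reference.molecule_id)
            )
            continue
        try:
            ens = embed_and_sample(rec, n_conformers=n_conformers, seed=seed)
        except Exception as err:
            skipped.append((rec.molecule_id, str(err)))
            continue
        mol = Chem.AddHs(Chem.MolFromSmiles(rec.smiles))
        mcs = rdFMCS.FindMCS([mol, ref_mol], timeout=10)
        patt = Chem.MolFromSmarts(mcs.smartsString)
        if patt is None:
            skipped.append((rec.molecule_id, "no common substructure"))
            continue
        atom_map = list(zip(mol.GetSubstructMatch(patt),
                            ref_mol.GetSubstructMatch(patt)))
        if len(atom_map) < 3:
            skipped.append((rec.molecule_id, "common substructure too small"))
            continue
        aligned, _ = align_to_reference(ens, ref_conf, atom_map,
                                        reference_id=reference.molecule_id)
        ensembles.append(aligned)
    return ensembles, skipped, reference.molecule_id


def _stage_conformers(cfg: RunConfig, state: dict, d: Path) -> None:
    series = _congeneric_series(state["records"])
    ensembles, skipped, reference_id = build_aligned_ensembles(
        series, cfg.n_conformers, cfg.seed_conformers
    )
    (d / "alignment.json").write_text(json.dumps({
        "reference": reference_id,
        "n_aligned": len(ensembles),
        "skipped": skipped,
    }, indent=2))
    state["ensembles"] = ensembles
    state["series"] = [r for r in series
                       if r.molecule_id in {e.molecule_id for e in ensembles}]


def _stage_fields(cfg: RunConfig, state: dict, d: Path) -> None:
    ensembles = state["ensembles"]
    probe = ProbeSpec(charge=cfg.probe_charge, lj_epsilon=cfg.probe_epsilon,
                      lj_sigma=cfg.probe_sigma, truncation=cfg.truncation)
    grid = build_grid(ensembles, spacing=cfg.grid_spacing, margin=cfg.grid_margin)
    fm = field_matrix(ensembles, grid, probe, mode=cfg.field_mode)
    y = pd.Series({r.molecule_id: r.pic50 for r in state["series"]})
    pruned, trace = prune_columns(fm, variance_floor=cfg.variance_floor,
                                  correlation_ceiling=cfg.correlation_ceiling,
                                  y=y.loc[fm.values.index])
    pruned.to_csv(d / "field_matrix_pruned.csv")
    (d / "field_meta.json").write_text(json.dumps({
        "mode": fm.mode, "grid_dims": grid.dims, "grid_origin": grid.origin,
        "spacing": grid.spacing, "n_columns_raw": fm.values.shape[1],
        "n_columns_pruned": pruned.shape[1],
        "metadata": {k: str(v) for k, v in fm.metadata.items()},
        "prune_trace": trace,
    }, indent=2))
    state["field_matrix"] = fm
    state["field_pruned"] = pruned
    state["field_grid"] = grid
    state["field_y"] = y.loc[fm.values.index]


def _stage_pls(cfg: RunConfig, state: dict, d: Path) -> None:
    X, y = state["field_pruned"], state["field_y"]
    cols, trace = select_variables(X, y, max_features=cfg.max_field_features)
    Xs = X[cols]
    n_lv, scan = choose_n_lv(Xs, y, max_lv=cfg.max_lv)
    model = fit_pls(Xs, y, n_lv)
    summary = summarize_model(model, Xs, y)
    summary.to_json(d / "pls_summary.json")
    q2_null = y_randomization(Xs.to_numpy(float), y.to_numpy(float), n_lv,
                              n_permutations=20, seed=cfg.seed_train)
    (d / "y_randomization.json").write_text(json.dumps({
        "q2_null_max": float(q2_null.max()),
        "q2_null_median": float(np.median(q2_null)),
        "fraction_below_0.2": float((q2_null <= 0.2).mean()),
    }, indent=2))
    maps = coefficient_map(model, state["field_grid"])
    for etype, arr in maps.items():
        write_cube(d / f"coefficients_{etype}.cube", state["field_grid"],
                   arr.ravel(), comment=f"PLS coefficients, {etype} field")
    state["pls_summary"] = summary


def run_field_recovery(
    seed: int = 0,
    n_conformers: int = 4,
    grid_spacing: float = 1.5,
    grid_margin: float = 3.0,
    effect_sizes: tuple[float, ...] = (1.5, -1.2, 1.0),
    noise_sd: float = 0.3,
    n_permutations: int = 50,
    max_lv: int = 5,
    max_columns: int = 40,
) -> dict:
    """Planted-coefficient recovery experiment on the congeneric series.

    The field matrix of the congeneric series is pruned first (variance
    floor, then de-correlation at ceiling 0.9, keeping each correlated grid
    neighbourhood's highest-variance member), a linear activity is planted on
    surviving descriptor columns (standardised effects ``effect_sizes`` plus
    N(0, noise_sd) noise), and a PLS model with LOO-Q²-selected latent
    variables is fitted on all surviving columns.  Planting after pruning
    defines the generative truth over the model's own descriptor space, so
    "recovered at its grid location" is well-posed: near-duplicate grid
    columns (|r| > 0.9) that could silently stand in for a planted one are
    gone before the response exists.  Reports LOO Q², whether the sign of
    every planted coefficient is recovered at its own grid location, and the
    y-randomisation null.
    """
    from .pls import cross_validate
    from .synthetic import plant_field_response

    data = generate_activity_table(PlantedSARSpec(seed=seed))
    records, _ = curate(data.table)
    series = _congeneric_series(records)
    ensembles, _, _ = build_aligned_ensembles(series, n_conformers, seed)
    grid = build_grid(ensembles, spacing=grid_spacing, margin=grid_margin)
    fm = field_matrix(ensembles, grid, ProbeSpec(), mode="4D")

    pruned, _ = prune_columns(fm, correlation_ceiling=0.9)
    # restrict to the most variable grid regions so the column count stays
    # commensurate with the series size (noise dilution otherwise dominates
    # the latent-variable estimates at n ~ 28)
    keep = pruned.var(axis=0).sort_values(ascending=False).index[:max_columns]
    pruned = pruned[keep]
    y, planted = plant_field_response(
        pruned, effect_sizes=effect_sizes, noise_sd=noise_sd, seed=seed
    )
    n_lv, _ = choose_n_lv(pruned, y, max_lv=max_lv)
    model = fit_pls(pruned, y, n_lv)
    cv = cross_validate(pruned.to_numpy(dtype=float), y.to_numpy(), n_lv)
    coef = dict(zip(model.feature_names, model.coefficients))
    signs = {
        str(c): bool(c in coef and np.sign(coef[c]) == np.sign(b))
        for c, b in planted.items()
    }
    q2_null = y_randomization(pruned.to_numpy(dtype=float), y.to_numpy(),
                              n_lv, n_permutations=n_permutations, seed=seed)
    return {
        "n_compounds": len(series),
        "n_lv": n_lv,
        "q2": float(cv["q2"]),
        "press_cv": float(cv["press_cv"]),
        "planted": {str(c): b for c, b in planted.items()},
        "signs_recovered": signs,
        "all_signs_recovered": all(signs.values()),
        "null_q2_max": float(q2_null.max()),
        "null_fraction_below_0.2": float((q2_null <= 0.2).mean()),
        "model": model,
        "grid": grid,
    }


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "physchem": _stage_physchem,
    "split": _stage_split,
    "classify": _stage_classify,
    "ad": _stage_ad,
    "csn": _stage_csn,
    "conformers": _stage_conformers,
    "fields": _stage_fields,
    "pls": _stage_pls,
}
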