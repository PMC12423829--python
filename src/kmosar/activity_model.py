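"""Supervised activity classifier with interpretable post-hoc analysis.

The modeling chain mirrors standard ligand-based practice: descriptor
pretreatment (non-numeric / missing / quasi-constant removal), two-stage
feature selection (mutual information, then tree-ensemble importance above a
cutoff), a diagnostic train/test split visualised by PCA + k-means over
fingerprint similarity, a random-forest classifier tuned by seeded random
search over the standard hyperparameter ranges with 5-fold cross-validation,
partial-dependence curves, and exact Shapley attributions computed from the
trees' cover-weighted conditional expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "ShapExplanation",
    "pretreat",
    "select_features",
    "split_and_map",
    "train_classifier",
    "evaluate",
    "metrics_from_confusion",
    "partial_dependence",
    "explain",
    "tree_shapley_values",
    "DEFAULT_SEARCH_SPACE",
]

# hyperparameter ranges for the forest, inclusive
DEFAULT_SEARCH_SPACE: dict[str, tuple[int, int]] = {
    "n_estimators": (10, 100),
    "max_depth": (2, 32),
    "min_samples_split": (2, 16),
    "min_samples_leaf": (1, 16),
}

IMPORTANCE_CUTOFF = 0.120  # on max-normalised importances


@dataclass
class FeatureMatrix:
    values: pd.DataFrame
    selection_trace: list[dict] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


class PretreatmentError(ValueError):
    pass


def pretreat(matrix: pd.DataFrame, quasi_constant_threshold: float = 0.99) -> FeatureMatrix:
    """Remove non-numeric, missing-valued and quasi-constant columns.

    A column is quasi-constant when its most frequent value covers more than
    ``quasi_constant_threshold`` of the rows.  The trace records every removal.
    """
    trace: list[dict] = []
    survivors = []
    n = len(matrix)
    for col in matrix.columns:
        series = matrix[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if not pd.api.types.is_numeric_dtype(series) and numeric.isna().any():
            trace.append({"stage": "non-numeric", "feature": col})
            continue
        if numeric.isna().any() or np.isinf(numeric.to_numpy(dtype=float)).any():
            trace.append({"stage": "missing", "feature": col})
            continue
        top = numeric.value_counts(normalize=True).iloc[0]
        if top > quasi_constant_threshold:
            trace.append({"stage": "quasi-constant", "feature": col,
                          "criterion": float(top)})
            continue
        survivors.append(col)
    if not survivors:
        stages = [t["stage"] for t in trace]
        dominant = max(set(stages), key=stages.count) if stages else "empty input"
        raise PretreatmentError(
            f"all {n and len(matrix.columns)} columns removed; dominant stage: {dominant}"
        )
    out = matrix[survivors].apply(pd.to_numeric)
    trace.append({"stage": "pretreat-kept", "features": list(survivors)})
    return FeatureMatrix(values=out, selection_trace=trace)


class SelectionError(ValueError):
    pass


def select_features(
    matrix: FeatureMatrix | pd.DataFrame,
    labels,
    importance_cutoff: float = IMPORTANCE_CUTOFF,
    top_k: int | None = 8,
    seed: int = 0,
) -> FeatureMatrix:
    """Two-stage feature selection.

    Stage 1 ranks features by mutual information with the class label and
    keeps those above the median of the positive MI scores.  Stage 2 fits a
    random forest and keeps features whose max-normalised importance exceeds
    ``importance_cutoff``; if ``top_k`` is set, at most the ``top_k`` most
    important survivors are retained.  Column order of the input does not
    affect the outcome (features are ranked, then restored to a sorted
    canonical order).
    """
    df = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    prior = list(matrix.selection_trace) if isinstance(matrix, FeatureMatrix) else []
    y = np.asarray(labels, dtype=int)
    cols = sorted(df.columns)  # canonical order: invariant to input ordering
    X = df[cols].to_numpy(dtype=float)

    # the kNN MI estimator is noisy for weak dependences at small k; widen the
    # neighbourhood and average seeded replicates to stabilise the ranking
    mi = np.mean(
        [mutual_info_classif(X, y, random_state=seed + k, n_neighbors=7)
         for k in range(3)],
        axis=0,
    )
    positive = mi[mi > 0]
    mi_floor = float(np.median(positive)) if positive.size else 0.0
    stage1 = [c for c, m in zip(cols, mi) if m > 0 and m >= mi_floor]
    trace = prior + [{
        "stage": "mutual-information",
        "scores": dict(zip(cols, map(float, mi))),
        "criterion": mi_floor,
        "kept": stage1,
    }]
    if not stage1:
        raise SelectionError("no feature has positive mutual information with the label")

    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(df[stage1].to_numpy(dtype=float), y)
    imp = rf.feature_importances_
    norm = imp / imp.max() if imp.max() > 0 else imp
    scored = sorted(zip(stage1, norm), key=lambda t: (-t[1], t[0]))
    # drop (near-)duplicate survivors: collinear pairs carry no extra
    # information and break downstream leverage computations
    stage2: list[str] = []
    dropped_dup: list[str] = []
    for c, v in scored:
        if v <= importance_cutoff:
            continue
        x = df[c].to_numpy(dtype=float)
        redundant = any(
            abs(np.corrcoef(x, df[k].to_numpy(dtype=float))[0, 1]) > 0.999
            for k in stage2
        )
        if redundant:
            dropped_dup.append(c)
        else:
            stage2.append(c)
    if top_k is not None:
        stage2 = stage2[:top_k]
    trace.append({
        "stage": "importance",
        "scores": {c: float(v) for c, v in zip(stage1, norm)},
        "criterion": importance_cutoff,
        "kept": stage2,
        "dropped_collinear": dropped_dup,
    })
    if not stage2:
        top5 = scored[:5]
        raise SelectionError(
            "no feature importance above cutoff "
            f"{importance_cutoff}; top scores: {top5}"
        )
    kept_sorted = sorted(stage2)
    return FeatureMatrix(values=df[kept_sorted].copy(), selection_trace=trace)


# --------------------------------------------------------------------------
# Split diagnostics: fingerprint similarity -> PCA -> k-means
# --------------------------------------------------------------------------

def morgan_fingerprints(smiles_list, radius: int = 2, n_bits: int = 2048):
    """Circular (ECFP4-style) fingerprints for the split diagnostics."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def similarity_matrix(fps) -> np.ndarray:
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        sim[i, i + 1:] = row
        sim[i + 1:, i] = row
    return sim


@dataclass
class SplitMap:
    train_ids: list[str]
    test_ids: list[str]
    embedding: pd.DataFrame     # molecule_id -> (pc1, pc2)
    cluster_labels: pd.Series   # molecule_id -> cluster


def split_and_map(
    records,
    n_test: int = 28,
    k_clusters: int = 5,
    seed: int = 42,
) -> SplitMap:
    """Random train/test split with a PCA + k-means chemical-space map.

    The 2D embedding is the top-2 principal components of the pairwise
    Tanimoto similarity matrix of circular fingerprints; k-means (seeded)
    labels chemical-space groupings.  Every cluster is guaranteed at least
    one training compound (memberships are rebalanced if the random split
    leaves a cluster test-only).
    """
    ids = [r.molecule_id for r in records]
    smiles = [r.smiles for r in records]
    n = len(ids)
    if n_test >= n:
        raise ValueError(f"n_test={n_test} must be < n_records={n}")
    if k_clusters > n:
        raise ValueError(f"k_clusters={k_clusters} exceeds n_records={n}")

    sim = similarity_matrix(morgan_fingerprints(smiles))
    emb = PCA(n_components=2, random_state=seed).fit_transform(sim)
    clusters = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10).fit_predict(sim)

    rng = np.random.default_rng(seed)
    test_idx = set(map(int, rng.choice(n, size=n_test, replace=False)))
    # every cluster must keep >= 1 training member
    for c in range(k_clusters):
        members = [i for i in range(n) if clusters[i] == c]
        if members and all(i in test_idx for i in members):
            test_idx.discard(members[0])
            for j in range(n):
                if j not in test_idx and clusters[j] != c:
                    test_idx.add(j)
                    break
    train_ids = [ids[i] for i in range(n) if i not in test_idx]
    test_ids = [ids[i] for i in sorted(test_idx)]
    return SplitMap(
        train_ids=train_ids,
        test_ids=test_ids,
        embedding=pd.DataFrame(emb, index=ids, columns=["pc1", "pc2"]),
        cluster_labels=pd.Series(clusters, index=ids, name="cluster"),
    )


# --------------------------------------------------------------------------
# Training, metrics
# --------------------------------------------------------------------------

def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from raw confusion counts."""
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return tp, fp, fn, tn


def _auc(y_true, scores) -> float:
    """Rank-based AUC (Mann-Whitney)."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


@dataclass
class ClassifierReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: tuple[int, int, int, int]
    cv_fold_metrics: list[dict]
    hyperparameters: dict
    cv_mean_accuracy: float = float("nan")


def evaluate(model, X, y, threshold: float = 0.5) -> ClassifierReport:
    """Score a fitted classifier on (X, y) at the given probability cutoff."""
    X = np.asarray(X, dtype=float)
    proba = model.predict_proba(X)[:, 1]
    pred = (proba >= threshold).astype(int)
    tp, fp, fn, tn = confusion_counts(y, pred)
    m = metrics_from_confusion(tp, fp, fn, tn)
    return ClassifierReport(
        accuracy=m["accuracy"], precision=m["precision"], recall=m["recall"],
        f1=m["f1"], auc=_auc(y, proba), confusion=(tp, fp, fn, tn),
        cv_fold_metrics=[], hyperparameters=dict(model.get_params()),
    )


def train_classifier(
    X,
    labels,
    search_space: dict[str, tuple[int, int]] | None = None,
    n_trials: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Tune a random forest by seeded random search and fit on all data.

    Candidates are drawn uniformly from the inclusive integer ranges in
    ``search_space``; each is scored by mean accuracy over a stratified
    ``cv_folds``-fold cross-validation, and the best is refit on the full
    training set.  The report carries per-fold metrics of the winner and the
    training-set confusion at probability cutoff 0.5.
    """
    space = dict(DEFAULT_SEARCH_SPACE if search_space is None else search_space)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(seed)
    trials = [
        {k: int(rng.integers(lo, hi + 1)) for k, (lo, hi) in space.items()}
        for _ in range(n_trials)
    ]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best_params, best_score, best_fold_metrics = None, -np.inf, []
    for params in trials:
        fold_metrics = []
        for tr, va in folds:
            clf = RandomForestClassifier(random_state=seed, **params)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[va])
            tp, fp, fn, tn = confusion_counts(y[va], pred)
            fold_metrics.append(metrics_from_confusion(tp, fp, fn, tn))
        score = float(np.mean([m["accuracy"] for m in fold_metrics]))
        if score > best_score:
            best_score, best_params, best_fold_metrics = score, params, fold_metrics

    model = RandomForestClassifier(random_state=seed, **best_params)
    model.fit(X, y)
    report = evaluate(model, X, y)
    report.cv_fold_metrics = best_fold_metrics
    report.hyperparameters = dict(best_params)
    report.cv_mean_accuracy = best_score
    return model, report


# --------------------------------------------------------------------------
# Partial dependence
# --------------------------------------------------------------------------

def partial_dependence(
    model,
    X: pd.DataFrame,
    features,
    grid_points: int = 50,
):
    """Marginal effect of one or two features on P(active).

    For each grid value (``grid_points`` evenly spaced points spanning the
    observed range) the feature is clamped and the model's predicted
    probability is averaged over all training rows.  With two features a grid
    surface is returned.
    """
    if isinstance(features, str):
        features = [features]
    for f in features:
        if f not in X.columns:
            raise KeyError(f"unknown feature {f!r}; model features: {list(X.columns)}")
    if len(features) not in (1, 2):
        raise ValueError("partial dependence supports one or two features")

    grids = [
        np.linspace(X[f].min(), X[f].max(), grid_points) for f in features
    ]
    base = X.to_numpy(dtype=float)
    cols = [X.columns.get_loc(f) for f in features]
    if len(features) == 1:
        pd_vals = np.empty(grid_points)
        for i, v in enumerate(grids[0]):
            work = base.copy()
            work[:, cols[0]] = v
            pd_vals[i] = model.predict_proba(work)[:, 1].mean()
        return pd.DataFrame({features[0]: grids[0], "partial_dependence": pd_vals})
    surface = np.empty((grid_points, grid_points))
    for i, v0 in enumerate(grids[0]):
        for j, v1 in enumerate(grids[1]):
            work = base.copy()
            work[:, cols[0]] = v0
            work[:, cols[1]] = v1
            surface[i, j] = model.predict_proba(work)[:, 1].mean()
    return grids[0], grids[1], surface


# --------------------------------------------------------------------------
# Exact tree-Shapley attributions
# --------------------------------------------------------------------------

MAX_SHAPLEY_FEATURES = 16  # 2^p conditional expectations per tree


@dataclass
class ShapExplanation:
    base_value: float
    per_feature_contribution: pd.Series
    feature_values: pd.Series

    @property
    def prediction(self) -> float:
        return float(self.base_value + self.per_feature_contribution.sum())


def _leaf_prob(tree, node: int, class_index: int = 1) -> float:
    v = tree.value[node].ravel()
    total = v.sum()
    return float(v[class_index] / total) if total > 0 else 0.0


def _subset_expectations(tree, X: np.ndarray, n_features: int) -> np.ndarray:
    """v[S, sample]: cover-weighted conditional expectation of P(class 1).

    For feature subset S the tree is descended following the sample where the
    split feature is in S and branching with training-cover weights where it
    is not — the path-dependent valuation that makes tree Shapley exact.
    """
    n_subsets = 1 << n_features
    n_samples = X.shape[0]
    v = np.empty((n_subsets, n_samples))
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples

    # per-node class-1 probability
    probs = np.array([_leaf_prob(tree, i) for i in range(tree.node_count)])

    def descend(node: int, mask: int) -> np.ndarray:
        if left[node] == -1:  # leaf
            return np.full(n_samples, probs[node])
        f = feat[node]
        if mask & (1 << f):
            out = np.empty(n_samples)
            go_left = X[:, f] <= thr[node]
            lvals = descend(left[node], mask)
            rvals = descend(right[node], mask)
            out[go_left] = lvals[go_left]
            out[~go_left] = rvals[~go_left]
            return out
        wl = cover[left[node]] / cover[node]
        return wl * descend(left[node], mask) + (1 - wl) * descend(right[node], mask)

    for mask in range(n_subsets):
        v[mask] = descend(0, mask)
    return v


def tree_shapley_values(model, X) -> tuple[float, np.ndarray]:
    """Exact Shapley attributions of P(active) for a tree ensemble.

    Returns ``(base_value, phi)`` with ``phi`` of shape (n_samples,
    n_features); ``base_value + phi.sum(1)`` equals ``predict_proba[:, 1]``
    exactly.  The valuation of a coalition is the ensemble's cover-weighted
    conditional expectation (see :func:`_subset_expectations`), so the base
    value is the expectation of the model output over the training
    distribution as encoded by the trees.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    # scikit-learn casts inputs to float32 at prediction time; round through
    # float32 so threshold comparisons route exactly as predict_proba does
    X = X.astype(np.float32).astype(np.float64)
    p = X.shape[1]
    if p > MAX_SHAPLEY_FEATURES:
        raise ValueError(
            f"exact enumeration supports up to {MAX_SHAPLEY_FEATURES} features, got {p}"
        )
    # Shapley kernel weights |S|! (p-|S|-1)! / p!
    w = np.array([
        math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
        for k in range(p)
    ])
    subset_size = np.array([bin(m).count("1") for m in range(1 << p)])
    masks_without = [
        np.array([m for m in range(1 << p) if not m & (1 << i)]) for i in range(p)
    ]

    phi = np.zeros((X.shape[0], p))
    base = 0.0
    estimators = model.estimators_
    for est in estimators:
        v = _subset_expectations(est.tree_, X, p)
        base += float(v[0, 0])  # empty coalition: sample-independent
        for i in range(p):
            masks = masks_without[i]
            gains = v[masks | (1 << i)] - v[masks]
            phi[:, i] += w[subset_size[masks]] @ gains
    n_est = len(estimators)
    return base / n_est, phi / n_est


def explain(model, row: pd.Series, feature_names=None) -> ShapExplanation:
    """Shapley explanation of a single compound's predicted activity."""
    if isinstance(row, pd.Series):
        values = row.to_numpy(dtype=float)
        names = list(row.index)
    else:
        values = np.asarray(row, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(len(values))
        ]
    if len(names) != model.n_features_in_:
        raise ValueError(
            f"row has {len(names)} features, model expects {model.n_features_in_}"
        )
    base, phi = tree_shapley_values(model, values[None, :])
    return ShapExplanation(
        base_value=float(base),
        per_feature_contribution=pd.Series(phi[0], index=names),
        feature_values=pd.Series(values, index=names),
    )


def reference_compounds(records, query_smiles: str):
    """Most similar (max Tanimoto, circular fp) and most active dataset
    molecules, for side-by-side display next to a query prediction."""
    fps = morgan_fingerprints([r.smiles for r in records])
    qfp = morgan_fingerprints([query_smiles])[0]
    sims = DataStructs.BulkTanimotoSimilarity(qfp, fps)
    i_sim = int(np.argmax(sims))
    i_act = int(np.argmax([r.pic50 for r in records]))
    return {
        "most_similar": records[i_sim],
        "similarity": float(sims[i_sim]),
        "most_active": records[i_act],
    }
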