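# Methods

This note documents the models, conventions and numerical choices behind
`kmosar`, and what the synthetic-data experiments do and do not demonstrate.

## Curation

IC50 values are taken in nM and converted as pIC50 = −log₁₀(IC50·10⁻⁹).
Rows are removed when the IC50 is missing, non-positive, unparseable, or
censored (any value whose text carries `<`, `>`, `~`, `≤`, `≥` or an
explicit range); structures failing SMILES parsing are removed; remaining
rows are deduplicated on the toolkit's default canonical SMILES (the RDKit
version used is written into the log header, since canonical forms can shift
between releases). When one structure carries several measurements we keep
the geometric mean if all values agree within one log unit and drop the set
entirely otherwise — replicate assay scatter within a log unit is normal,
larger spread usually signals an assay-condition mismatch. The
lexicographically smallest compound ID survives a merge, which keeps
curation idempotent. Compounds with pIC50 ≥ 7.6 (IC50 ≈ 25 nM) are labelled
active; the boundary itself is active.

## Physicochemical profile

Log P is the Crippen atom-contribution estimate; ring counts use SSSR;
H-bond donors/acceptors, rotatable bonds and TPSA are the toolkit
definitions. Pearson correlations are computed pairwise from centred sums;
a zero-variance vector raises an error rather than returning 0, because a
silent 0 would be read as "no association" when the quantity is undefined.

## Activity classifier

* **Pretreatment** removes non-numeric and missing-valued columns and
  quasi-constant columns (most frequent value covering > 99 % of rows).
* **Feature selection** is two-stage. Stage 1 keeps features whose mutual
  information with the class label is positive and at or above the median of
  the positive scores. The kNN MI estimator is run with `n_neighbors = 7`
  and averaged over three seeded replicates: at the default three
  neighbours the estimator frequently returns exactly zero for weak but real
  marginal dependences at a few hundred samples, which makes rankings
  unstable. Stage 2 fits a 200-tree forest and keeps features whose
  importance, normalised so the largest equals 1, exceeds 0.120 (raw
  impurity importances sum to 1 and would make any fixed cutoff meaningless
  as the feature count changes); an optional top-k (default 8) truncates the
  survivors. Selection is invariant to input column order: candidates are
  ranked on a sorted canonical ordering.
* **Split diagnostics** compute 2048-bit radius-2 circular fingerprints, the
  pairwise Tanimoto similarity matrix, its top-2 principal components for
  plotting, and seeded k-means (default k = 5) cluster labels. The random
  test split (default 28 compounds) is adjusted, if necessary, so every
  cluster retains at least one training compound.
* **Training** draws hyperparameters uniformly from the standard ranges
  (trees 10–100, depth 2–32, min-split 2–16, min-leaf 1–16), scores each
  candidate by mean accuracy over stratified 5-fold cross-validation, and
  refits the winner on all training data. Class probability cutoff is 0.5.
* **Partial dependence** fixes the feature at each of 50 evenly spaced grid
  values spanning its observed range and averages predicted P(active) over
  the training rows; the two-feature variant returns a 50×50 surface.
* **Shapley explanations** are exact. For a coalition S the value function
  is the forest's cover-weighted conditional expectation: the tree is
  descended following the compound where the split feature is in S and
  branching with training-cover weights where it is not. All 2^p coalition
  values per tree are evaluated by a vectorised descent (p ≤ 16; the
  pipeline uses p = 8) and combined with exact factorial weights, so
  base + Σφ equals predict_proba to machine precision. Inputs are rounded
  through float32 before threshold comparisons because scikit-learn predicts
  in float32; without this, a value adjacent to a split threshold can route
  to a different leaf than the model's own prediction and break additivity.

## Applicability domain

Leverage h_i = x_iᵀ(XᵀX)⁻¹x_i on the unscaled selected-descriptor matrix
(a scaling toggle exists). The warning threshold is h\* = 3p/n without
intercept augmentation — with p = 8 descriptors and n = 109 training
compounds this gives 0.220, and the intercept-augmented alternative
3(p+1)/n would not. Training leverages sum to p for a full-rank matrix,
which the tests use as an algebraic check; rank-deficient input fails with
the collinear columns named (QR with pivoting).

## Chemical space networks

Nodes are compounds; an edge joins two compounds when the Tanimoto
coefficient of their path-based (RDKit topological) fingerprints is at
least the edge threshold (default 0.68). Circular fingerprints are used for
the classifier's split map, path fingerprints here; both are configurable.
Edges are tiered thick (Tc ≥ 0.9), medium (0.7 < Tc < 0.9), thin
(Tc ≤ 0.7); an edge at exactly 0.7 is thin, which also resolves the overlap
between the 0.68 edge threshold and the thin band. Connected components are
reported in size order as "subgraphs"; greedy modularity communities are
computed over the whole graph and reported separately. Tier percentages are
rounded to 2 d.p. for reporting. Spring layouts are exported with a fixed
seed.

## Field descriptors (3D/4D)

Conformer ensembles stand in for molecular-dynamics conformational
ensemble profiles: ETKDG distance-geometry embedding (seeded), MMFF94
refinement (UFF fallback), Gasteiger partial charges renormalised to the
formal molecular charge, and per-element Lennard-Jones parameters from a
UFF-style table (σ = x_min/2^{1/6}). These are desk-scale surrogates for
MD ensembles and quantum-chemical charges; the substitution is recorded in
the matrix metadata, and no claim is made that the resulting fields match
ones derived from DFT geometries.

Each ensemble is rigidly superposed (Kabsch, proper rotation) on the most
active compound of the series over their maximum common substructure; at
least three non-collinear mapped atoms are required. The grid is the
axis-aligned box over all aligned atoms plus a margin (defaults: spacing
1.0 Å, margin 4.0 Å; dims = ceil(extent/spacing)+1). Probe defaults: an
sp³-carbon-like site, ε = 0.1094 kcal/mol, σ = 3.4 Å, charge +1 e. Energies
use Lorentz–Berthelot combination and the Coulomb constant
332.0636 kcal·Å·mol⁻¹·e⁻², and are clamped to ±30 kcal/mol (configurable)
to tame the r⁻¹² singularity; a grid point within 10⁻⁶ Å of an atom gets
the clamped value. 4D descriptors are arithmetic means of per-conformer
energies, so the 4D matrix is exactly the average of the per-conformer 3D
matrices. Column pruning removes variance below a floor (default 10⁻⁴) and
collapses groups correlated above a ceiling (default 0.99) to one member —
the most response-correlated member when a response is supplied, else the
highest-variance one. Units are kcal/mol and Å throughout.

## PLS chemometrics

Single-response NIPALS on centred (optionally autoscaled; off by default
since field columns share physical units) data; coefficients are returned in
original variable space via b = W(PᵀW)⁻¹q. Reported statistics follow the
conventions: R² = 1 − SSE/SSY, RMSEC = √(SSE/n), SEC = √(SSE/(n−nLV−1)),
F = [(SSY−SSE)/nLV]/[SSE/(n−nLV−1)] — latent variables are counted as model
degrees of freedom — and, from the leave-one-out loop (each fold refit from
scratch), PRESS, Q² = 1 − PRESS/SSY and RMSECV = √(PRESS/n). Leave-N-out is
available via the same routine. External predictivity is
R²_pred = 1 − Σ(y_t−ŷ_t)²/Σ(y_t−ȳ_train)². The number of latent variables
is chosen as the LOO-Q² maximiser up to a cap (default 10). Variable
selection ranks columns by |correlation with y|, keeps the top 80 as a
candidate pool, and greedily adds the candidate giving the largest LOO-Q²
improvement until no candidate improves by 10⁻⁴ or 15 columns are kept.
y-randomisation refits the model on permuted responses; a real model's Q²
should sit far above the permuted distribution.

## Synthetic data and what it shows

The generator emulates a curated inhibitor table: five structurally
dissimilar scaffold families (so path-fingerprint similarity at Tc ≥ 0.68
separates them into pure network components), one family forced to ≥ 20
members as a congeneric series, positional substituent decoration
(halogens, methyl, methoxy, trifluoromethyl, carboxyl), and
pIC50 = baseline + family offset + Σ substituent effects + N(0, σ) with
σ = 0.3 by default, baseline 7.3 and family offsets spreading activities
across ≈ 5–9 so both potency classes are populated at the 7.6 cutoff.
IC50 is emitted in nM as 10^(9−pIC50). Five percent of rows are re-emitted
as duplicate structures and five percent as missing-IC50 rows so curation
has real work; counts are rounded, giving 137 + 7 + 7 raw rows at the
default size. With σ = 0 an ordinary regression on the substituent
indicator matrix recovers the planted coefficients to 10⁻⁹, which anchors
the generator itself.

The field-recovery experiment plants a linear activity directly on field
descriptor columns of the congeneric series: the field matrix is pruned
first (variance floor, correlation ceiling 0.9, then restriction to the 40
highest-variance columns so the column count stays commensurate with the
~28-member series), and y = 7.0 + Σ β_j z_j + N(0, 0.3) is built on three
mutually decorrelated surviving columns with standardised effects
(1.5, −1.2, 1.0). Planting after pruning makes "the sign is recovered at
its grid location" well-posed — no near-duplicate column can silently stand
in for a planted one — and the strong effect sizes put the true model's own
LOO Q² clearly above the acceptance band, so the experiment probes the
recovery machinery rather than a particular noise draw. Across seeds the
fitted pruned-matrix PLS model reaches Q² ≈ 0.82–0.96 and recovers all
three planted signs.

Passing these experiments shows the machinery is correct — formulas,
cross-validation loops, alignment, grid energetics, attribution identities —
on data whose generative truth is known. It does not show that the
force-field-level ensembles or empirical charges reproduce results obtained
from quantum-chemically optimised geometries and MD ensembles, nor that
synthetic families mimic real hKMO pharmacophores; the families are
structural constructs only.

## Known limitations

* The exact Shapley explainer enumerates 2^p coalitions per tree and is
  limited to 16 features (the pipeline uses 8).
* Conformer generation can fail for exotic structures; such molecules are
  skipped and reported, not silently dropped.
* The acceptance experiments use a coarse grid (1.5 Å spacing, 3 Å margin)
  and 4-conformer ensembles to keep a full run in minutes on one CPU;
  production analyses should use the 1.0 Å / 4.0 Å defaults and larger
  ensembles.
* Williams-plot residual axes are not produced for the classifier (no
  continuous residual exists); the leverage scatter data are exported
  instead.
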