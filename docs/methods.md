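# Methods

## Problem setting

A single drug target — the motivating case is the norepinephrine
transporter (NET/SLC6A2), a solute carrier with chemically monotonous
known ligands — rarely has enough bioactivity data to train a regression
model that generalizes to new chemotypes. Proteochemometric (PCM)
modeling mitigates this by regressing over compound–protein *pairs*:
each training row concatenates compound descriptors and protein
descriptors, so ligands of related proteins inform predictions for the
seed target. The open question this package operationalizes is *which*
related proteins to include: too few and the chemical space stays
narrow, too many and unrelated pharmacology dilutes the signal. The
selection is made data-driven — candidate protein sets are generated
from sequence similarity, each candidate's usable signal is measured by
cross-validation, and the largest set whose score is statistically
comparable to the best is kept.

## Curation model

A data point is one (standardized compound, target) pair with a single
pChEMBL value (−log10 molar activity). When a pair carries measurements
of several activity types, only the highest-priority type is kept
(Ki > IC50 > EC50 > Kd) — lower-priority measurements are discarded,
not averaged in. Duplicate values within the chosen type are averaged.
The year attached to a merged record is the *earliest* year among the
duplicates, so temporal splits stay conservative: a compound known
early can never leak into the future test side. Compound
standardization (RDKit `rdMolStandardize`) keeps the largest organic
fragment, neutralizes protonation-state charges (the deliverable
convention is a neutral canonical parent, approximating a pH-7 rule
table), and emits canonical SMILES; the operation is idempotent, which
makes curation of an already-curated table the identity on pairs and
values.

## Descriptors

Compound blocks: extended-connectivity fingerprints (default ECFP-6 =
bond radius 3, 1024 bits) and an 8-column physicochemical block (MW,
cLogP, HBD, HBA, rotatable bonds, TPSA, ring count, heavy atoms).
Protein blocks: per-position residue encodings from the published
5-dimensional z-scales, compressed to fixed length by
autocross-correlation (ACC): for properties j,k and lag l ∈ 1..L,

    ACC(j,k,l) = mean_i ( x[i,j] − x̄_j ) ( x[i+l,k] − x̄_k ),

giving p²·L columns (default p = 5, L = 3 → 75). Centering by
per-property column means makes the transform invariant to constant
shifts; gap positions encode as zero vectors. An alignment-free
composition block (residue + dipeptide frequencies) is available in
place of web-service descriptors. No cross-term (compound × protein
product) columns are generated — nonlinear learners capture
interactions on their own, and cross-terms are poorly interpretable.
Tanimoto similarity of two all-zero fingerprints is defined as 1.0
(both molecules featureless at that resolution ⇒ maximally similar).

## Target selection

All-versus-all protein similarity uses Smith–Waterman local alignment
(BLOSUM62, gap open 11 / extend 1, raw score), symmetrized by the max
of the two orders. Raw alignment scores are database- and
length-specific, so network thresholds are always user-supplied inputs;
the historical sweep values (850/650/550/350/100) are shipped as
documented defaults only. A similarity network at threshold t has an
edge wherever score ≥ t; the candidate training set at t is the
connected component containing the seed. Components grow monotonically
as t falls, producing a nested chain.

The phylogenetic chain uses pairwise fractional-identity distances
(global alignment) → neighbor-joining tree. Because an NJ tree is
unrooted, "successive ancestors of the seed leaf" is ill-defined as
stated in rooted terms; layers are instead defined by topological
distance in the unrooted tree: layer k contains the seed plus every
leaf whose path from the seed leaf crosses at most k−1 internal nodes,
with consecutive identical layers merged. This reproduces the intended
behavior — a ladder-like family yields one-leaf-at-a-time growth, a
star topology yields a single non-trivial layer, and the final layer is
always the full leaf set.

Each candidate layer (networks and tree layers, deduplicated by
protein-set equality) is scored with a fixed out-of-the-box random
forest — 100 trees, √D features per split, minimum node size 1, no
depth cap — under seeded 10-fold cross-validation, reporting pooled
out-of-fold R² and RMSE. Layers under 20 records (configurable) are
marked unevaluable rather than aborting. Selection takes, among layers
with R² ≥ max(R²) − tolerance (default 0.01, the package's reading of
"comparable"), the one with the most records; more data at equal signal
is strictly better for downstream chemistry coverage.

## Modeling

Base regressors: random forest, gradient boosting, and partial least
squares (scikit-learn implementations; the GB grid maps the classic
xgboost grid onto `GradientBoostingRegressor`: trees → `n_estimators`,
learning rate → `learning_rate`, gamma → `min_impurity_decrease`,
depth → `max_depth`, data fraction → `subsample`, descriptor fraction →
`max_features`). Hyperparameter search is an exhaustive Cartesian grid
maximizing 5-fold CV R²; failed cells score −∞ and stay in the audit
table; ties resolve to the first cell in grid order. Feature selection
is greedy forward selection over descriptor *blocks* (max 25
iterations, stop after 3 consecutive non-improvements); selection runs
before the grid, and both trajectories are retained.

Stacking: for each base model, k = 10 fold-models are fit, each on
k−1 folds. The meta features are, per base, (mean, SD) of fold-model
predictions. At training time the mean column is the single out-of-fold
prediction — the only fully unleaked choice — while the SD pools all k
fold-models (a documented caveat: k−1 of them saw the row). At
inference both statistics pool all k fold-models. The default meta
learner is PLS over the 2·B meta columns; PLS is excluded as a *base*
by default (it underperforms without cross-terms) but remains available
by configuration. R² is always the coefficient of determination
1 − SS_res/SS_tot, never squared Pearson.

Validation splits: random holdout (seeded uniform); temporal (records
with year < cutoff train, cutoff and later test, missing years train —
default cutoff 2010); and target-based 70/30 — PCA retaining ≥ 90%
variance on protein descriptors, K-means with k = max(2, round(√p)),
whole clusters greedily assigned to the training side (largest record
count first) until its record share first reaches the requested
fraction. No protein ever appears on both sides.

## Screening

Libraries stream in batches (bounded memory); compounds predicted at or
above the affinity threshold are retained — the threshold is pChEMBL
7.00 (100 nM), and the boundary itself is kept ("better than 100 nM"
read inclusively, consistent with reported threshold-value compounds).
The novelty filter keeps hits whose nearest-training-compound Tanimoto
similarity s (ECFP-6, 1024 bits) lies strictly inside (0.5, 0.9): s ≥
0.9 is redundant with training chemistry, s ≤ 0.5 is outside the
model's applicability domain. Filtering runs before clustering (the
order is switchable). Survivors are clustered with HDBSCAN on Jaccard
distance of the fingerprints themselves — never on a 2-D embedding,
where density is an artifact — with minimum cluster size 19 and noise
allowed; a degenerate all-identical input is assigned a single cluster
directly, since HDBSCAN never selects its root. Per non-noise cluster
the top-predicted hit is flagged representative (ties: higher training
similarity, then lexicographically smallest SMILES). t-SNE is provided
for reporting only.

## Impedance dose–response analysis

Well impedance Z(t) becomes cell index CI = (Z − Z₀)/15 Ω.
"Normalized CI" divides by the last sample at or before substrate
addition (the instrument-software convention; division, not
subtraction — the chain is then invariant to consistent rescaling of
all impedances). The averaged vehicle/vehicle trace is subtracted
pointwise (linear resampling if grids differ). The response statistic
is the signed trapezoidal net AUC over the 30 minutes after
stimulation. Percent response anchors the substrate-only wells at 0%
and the reference-inhibitor wells at 100%. Per-concentration replicate
means (SEM reported alongside) are fit by least squares to

    R(c) = bottom + (top − bottom) / (1 + 10^−(log10 c + pIC50)),

the fixed pseudo-Hill-slope-1 sigmoid rising with concentration (an
inhibitor *enhances* the substrate response in this assay). Fitting
multi-starts over 13 pIC50 values spanning the tested concentrations
± 1 log unit; a fit is rejected if the pIC50 lands outside that span,
if responses are flat ("no concentration dependence"), or if the RMS
residual exceeds max(5%, 25% of the response span). Requirements: ≥ 4
distinct concentrations spanning ≥ 2 log units.

## Synthetic worlds

The generators emulate the statistical structure the pipeline assumes,
not realistic pharmacology. Proteins: i.i.d. point mutants of a random
120-residue seed at per-tier substitution rates (defaults 0.02 / 0.15
/ 0.45 for 3 + 4 + 4 proteins around the seed), so expected identity
falls tier by tier and alignment scores separate the tiers. Compounds:
a ~30-fragment grammar (substituted aryl/heteroaryl cores ×
amine-rich linkers × chain/ring tails — secondary-amine-heavy on
purpose, echoing aminergic-transporter chemotypes) producing valid,
standardizable SMILES. Bioactivities: pChEMBL = 6.5 + signal_sd·z +
ε, where z is the standardized latent readout w·bits + v·protein-ACC +
interaction term and ε ~ N(0, noise_sd); defaults signal_sd = 1,
noise_sd = 0.5 put the attainable R² near 0.8. Distant-tier proteins
are label-permuted decoys by default: their marginal label distribution
is intact but carries no signal, planting the ground truth that only
the seed + tight homologs + mid tier share chemistry. Activity-type
labels cycle through all four types and ~5% duplicate rows are
emitted to exercise the curation rules. Impedance plates synthesize
traces whose post-stimulation amplitude follows the fixed-slope
sigmoid exactly, with optional Gaussian amplitude noise in percent of
the control-to-reference window, so the analysis chain's recovery can
be checked against known pIC50s.

What a green test does *not* establish: real bioactivity data has
assay heterogeneity, activity cliffs, and series bias that the linear
latent model lacks; the protein family has no indels, so alignment
steps are never stressed by gaps; the grammar's chemical diversity is
tiny compared to a make-on-demand library. The standard "small" world
(12 proteins / 400 compounds / 2,000 records) builds in a few seconds.

## Numerical and design choices

- Global default seed 12345 for every stochastic stage; all estimators
  and fold splits are seeded, so reruns are bit-identical.
- Random forests bootstrap, so training-set replay is *near*-
  interpolating, not exact (R² ≈ 0.9 on tiny noiseless fixtures).
- Grid/selection CV scores use pooled out-of-fold predictions (one R²
  per configuration) rather than per-fold averaging.
- PLS meta-component count is capped at the meta-feature width.
- Feature selection accepts a block only on strict CV-R² improvement;
  the first block is always kept, so selection is never empty.
- Empty-union Tanimoto = 1.0; equal-grid vehicle subtraction is exact,
  otherwise linear interpolation; net AUC inserts the exact window
  endpoints before integrating.

## Known limitations

- Alignment-based protein descriptors assume equal-length (or
  right-padded) sequences; heavily gapped families should be aligned
  externally before encoding.
- The streaming screen bounds memory in the library but retains all
  passing hits; a threshold admitting most of a huge deck will still
  grow memory.
- HDBSCAN runs on a dense pairwise distance matrix; beyond ~20k kept
  hits the O(n²) memory dominates.
- The sklearn gradient-boosting surrogate differs from xgboost in
  regularization details; grid semantics are mapped, not identical.
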