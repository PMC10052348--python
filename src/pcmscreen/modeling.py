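"""Base and stacked PCM regressors, hyperparameter grids, and validation splits.

Three base algorithm families are supported — random forest, gradient
boosting, and partial least squares — with the screening-campaign grid
for each. Stacking turns the out-of-fold predictions of one or two base
models (per-row mean and standard deviation across a k-fold model bank)
into features for a second-level regressor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict

DEFAULT_SEED = 12345

ALGORITHMS = ("random_forest", "gradient_boosting", "partial_least_squares")

_ALLOWED_PARAMS = {
    "random_forest": {"n_estimators", "max_features", "min_samples_leaf", "max_depth"},
    "gradient_boosting": {
        "n_estimators", "learning_rate", "min_impurity_decrease",
        "max_depth", "subsample", "max_features",
    },
    "partial_least_squares": {"n_components"},
}

#: Full hyperparameter grids swept during optimization, per algorithm.
#: Random forest: trees, descriptors per split (sqrt/log2/fractions of D),
#: minimum node size, depth. Gradient boosting: trees, learning rate,
#: split-gain penalty, depth, row subsample, column subsample.
#: PLS: latent variable count.
TABLE1_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 250, 500, 1000],
        "max_features": ["sqrt", "log2", 0.1, 0.5, 0.9],
        "min_samples_leaf": [1, 5, 7],
        "max_depth": [5, 7, None],
    },
    "gradient_boosting": {
        "n_estimators": [100, 250, 500, 1000],
        "learning_rate": [0.1, 0.3, 0.5],
        "min_impurity_decrease": [0.0, 0.3, 0.5],
        "max_depth": [5, 7],
        "subsample": [0.1, 0.5, 1.0],
        "max_features": [0.5, 0.7],
    },
    "partial_least_squares": {
        "n_components": [100, 200, 300],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm plus hyperparameters (and the blocks it was trained on)."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    blocks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        bad = set(self.hyperparameters) - _ALLOWED_PARAMS[self.algorithm]
        if bad:
            raise ValueError(f"invalid hyperparameters for {self.algorithm}: {sorted(bad)}")


class FittedModel:
    """A fitted estimator with a uniform 1-D ``predict``."""

    def __init__(self, spec: ModelSpec, estimator):
        self.spec = spec
        self.estimator = estimator

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(features)).ravel()


def _make_estimator(spec: ModelSpec, seed: int):
    params = dict(spec.hyperparameters)
    if spec.algorithm == "random_forest":
        params.setdefault("max_features", "sqrt")
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **params)
    return PLSRegression(**params)


def train_base(
    spec: ModelSpec, features: np.ndarray, labels: np.ndarray, seed: int = DEFAULT_SEED
) -> FittedModel:
    """Fit one base regressor; deterministic for a given seed."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(features) < 10:
        raise ValueError("need at least 10 training rows")
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    if spec.algorithm == "partial_least_squares":
        n_components = int(spec.hyperparameters.get("n_components", 2))
        if n_components > min(features.shape):
            raise ValueError(
                f"PLS components ({n_components}) exceed the data rank bound "
                f"{min(features.shape)}"
            )
    est = _make_estimator(spec, seed)
    est.fit(features, labels)
    return FittedModel(spec, est)


def compute_metrics(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Coefficient of determination R2 and RMSE.

    R2 is 1 - SS_res/SS_tot (not squared Pearson); a constant observed
    vector makes it undefined and raises.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


def _cv_r2(spec: ModelSpec, features, labels, folds: int, seed: int) -> float:
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    est = _make_estimator(spec, seed)
    pred = np.asarray(cross_val_predict(est, features, labels, cv=cv)).ravel()
    r2, _ = compute_metrics(labels, pred)
    return r2


def grid_search(
    algorithm: str,
    grid: Mapping[str, Sequence],
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search maximizing k-fold cross-validated R2.

    Every cell of the Cartesian grid is evaluated; failures score -inf and
    are kept in the audit table. Ties resolve to the first cell in
    deterministic grid order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    names = list(grid)
    rows = []
    best_params, best_score = None, -np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        try:
            score = _cv_r2(ModelSpec(algorithm, params), features, labels, folds, seed)
        except Exception as exc:  # noqa: BLE001 — cell failure is data, not abort
            rows.append({**params, "cv_r2": -np.inf, "error": str(exc)})
            continue
        rows.append({**params, "cv_r2": score, "error": ""})
        if score > best_score:
            best_params, best_score = params, score
    table = pd.DataFrame(rows)
    if best_params is None:
        raise ValueError("every grid cell failed")
    return best_params, table


def stepwise_block_selection(
    candidate_blocks: Sequence[str],
    spec: ModelSpec,
    feature_matrix,
    labels: np.ndarray,
    max_iter: int = 25,
    patience: int = 3,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection over descriptor blocks by CV R2 gain.

    Each iteration tries adding every remaining block and keeps the one
    with the largest cross-validated R2, accepting it only if it improves
    on the incumbent. Stops after ``max_iter`` iterations, ``patience``
    consecutive non-improving iterations, or when no block remains. The
    single best first block is always kept.
    """
    if not candidate_blocks:
        raise ValueError("no candidate blocks")
    selected: list[str] = []
    remaining = list(candidate_blocks)
    best_r2 = -np.inf
    misses = 0
    trajectory = []

    def score(blocks: Sequence[str]) -> float:
        cols = np.hstack([feature_matrix.block(b) for b in blocks])
        return _cv_r2(spec, cols, labels, folds, seed)

    for iteration in range(1, max_iter + 1):
        if not remaining or misses >= patience:
            break
        scored = [(score(selected + [b]), b) for b in remaining]
        cand_r2, cand = max(scored, key=lambda t: (t[0], -remaining.index(t[1])))
        accepted = cand_r2 > best_r2
        trajectory.append(
            {"iteration": iteration, "block": cand, "cv_r2": cand_r2, "accepted": accepted}
        )
        if accepted:
            selected.append(cand)
            remaining.remove(cand)
            best_r2 = cand_r2
            misses = 0
        else:
            misses += 1
    return selected, pd.DataFrame(trajectory)


def make_meta_features(
    base_specs: Sequence[ModelSpec],
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, list[list[FittedModel]]]:
    """Out-of-fold stacking features: per-base prediction mean and spread.

    For each base model, k fold-models are fit, each on k-1 folds. For a
    training row the mean column is the prediction of the single
    fold-model that did not see it (unleaked), while the std column is
    the spread of that row's predictions across all k fold-models. At
    inference on new rows both statistics pool all k fold-models.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(features)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(cv.split(features))
    meta = np.empty((n, 2 * len(base_specs)), dtype=float)
    banks: list[list[FittedModel]] = []
    for b, spec in enumerate(base_specs):
        fold_models = []
        all_preds = np.empty((k, n), dtype=float)
        oof = np.empty(n, dtype=float)
        for f, (train_idx, test_idx) in enumerate(splits):
            model = train_base(spec, features[train_idx], labels[train_idx], seed=seed)
            fold_models.append(model)
            all_preds[f] = model.predict(features)
            oof[test_idx] = all_preds[f, test_idx]
        meta[:, 2 * b] = oof
        meta[:, 2 * b + 1] = all_preds.std(axis=0)
        banks.append(fold_models)
    return meta, banks


@dataclass
class StackedModel:
    """Base fold-model banks + a meta regressor over their predictions."""

    base_specs: tuple[ModelSpec, ...]
    meta_spec: ModelSpec
    fold_models: list[list[FittedModel]]
    meta_model: FittedModel
    k: int
    seed: int

    def meta_features(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        meta = np.empty((len(features), 2 * len(self.base_specs)), dtype=float)
        for b, bank in enumerate(self.fold_models):
            preds = np.stack([m.predict(features) for m in bank])
            meta[:, 2 * b] = preds.mean(axis=0)
            meta[:, 2 * b + 1] = preds.std(axis=0)
        return meta

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.meta_model.predict(self.meta_features(features))


def train_stacked(
    base_specs: Sequence[ModelSpec],
    meta_spec: ModelSpec,
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = DEFAULT_SEED,
) -> StackedModel:
    """Fit the two-level stack: k-fold base banks, then the meta model."""
    meta_train, banks = make_meta_features(base_specs, features, labels, k=k, seed=seed)
    if meta_spec.algorithm == "partial_least_squares":
        n_comp = int(meta_spec.hyperparameters.get("n_components", 2))
        n_comp = min(n_comp, meta_train.shape[1])
        meta_spec = ModelSpec(meta_spec.algorithm, {"n_components": n_comp}, meta_spec.blocks)
    meta_model = train_base(meta_spec, meta_train, labels, seed=seed)
    return StackedModel(
        base_specs=tuple(base_specs),
        meta_spec=meta_spec,
        fold_models=banks,
        meta_model=meta_model,
        k=k,
        seed=seed,
    )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test row assignment."""

    kind: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train/test overlap")


def split_random_holdout(n: int, fraction: float, seed: int = DEFAULT_SEED) -> SplitPlan:
    """Seeded uniform holdout; test size within 1 of fraction*n."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    return SplitPlan(
        kind="random_holdout",
        train_idx=np.sort(perm[n_test:]),
        test_idx=np.sort(perm[:n_test]),
        params={"fraction": fraction, "seed": seed},
    )


def split_temporal(years: Sequence[int | None], cut_year: int = 2010) -> SplitPlan:
    """Publication-year split: pre-cut rows train, cut year and later test.

    Rows without a year go to the training side (conservative: they can
    never inflate apparent prospective performance).
    """
    train, test = [], []
    for i, year in enumerate(years):
        if year is not None and year >= cut_year:
            test.append(i)
        else:
            train.append(i)
    if not train or not test:
        warnings.warn(f"temporal split at {cut_year} put all records on one side", stacklevel=2)
    return SplitPlan(
        kind="temporal",
        train_idx=np.array(train, dtype=int),
        test_idx=np.array(test, dtype=int),
        params={"cut_year": cut_year},
    )


def split_target_based(
    target_ids: Sequence[str],
    protein_descriptors: Mapping[str, np.ndarray],
    train_fraction: float = 0.7,
    seed: int = DEFAULT_SEED,
) -> SplitPlan:
    """Protein-level split via PCA-assisted K-means on protein descriptors.

    Proteins are clustered (PCA retaining >=90% variance, K-means with
    k = max(2, round(sqrt(p)))), then whole clusters are assigned to the
    training side — largest record count first — until the training
    record share first reaches ``train_fraction``. No protein ever sits
    on both sides.
    """
    proteins = sorted(set(target_ids))
    if len(proteins) < 2:
        raise ValueError("target-based split needs at least 2 proteins")
    mat = np.stack([np.asarray(protein_descriptors[p], dtype=float) for p in proteins])
    n_comp = min(len(proteins) - 1, mat.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(mat)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, 0.90) + 1) if len(cum) else 1
    scores = scores[:, :keep]
    k = min(max(2, round(np.sqrt(len(proteins)))), len(proteins))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    cluster_of = dict(zip(proteins, km.fit_predict(scores)))

    counts = pd.Series(list(target_ids)).value_counts()
    cluster_records: dict[int, int] = {}
    for p in proteins:
        cluster_records[cluster_of[p]] = cluster_records.get(cluster_of[p], 0) + int(counts[p])
    order = sorted(cluster_records, key=lambda c: (-cluster_records[c], c))

    n_total = len(target_ids)
    train_clusters: set[int] = set()
    share = 0.0
    for c in order[:-1]:
        train_clusters.add(c)
        share += cluster_records[c] / n_total
        if share >= train_fraction:
            break
    train = [i for i, t in enumerate(target_ids) if cluster_of[t] in train_clusters]
    test = [i for i, t in enumerate(target_ids) if cluster_of[t] not in train_clusters]
    return SplitPlan(
        kind="target_based",
        train_idx=np.array(train, dtype=int),
        test_idx=np.array(test, dtype=int),
        params={"train_fraction": train_fraction, "seed": seed, "k": k,
                "clusters": {p: int(cluster_of[p]) for p in proteins}},
    )
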