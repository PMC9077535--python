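"""Group-aware splitting, cross-validation, recursive feature elimination,
model adapters, and metric reporting.

Rows of the design matrix are keyed by (protein, sample); holding out 20%
of *samples* asks "can we predict new conditions for known proteins?",
while holding out 20% of *proteins* asks the much harder "can we predict
proteins the model has never seen?".  All splitting here is group-aware:
every row of a group travels to the same side of a split or fold, and the
disjointness of train/test groups is asserted on every call.

R^2 throughout is the squared Pearson correlation between predictions and
observations (the convention of caret-style regression summaries), which
differs from 1 - SS_res/SS_tot for biased predictors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ALGORITHMS",
    "SplitSpec",
    "FoldAssignment",
    "ModelSpec",
    "ModelBundle",
    "EvalMetrics",
    "RfeResult",
    "group_holdout",
    "group_kfold",
    "train",
    "evaluate",
    "importance",
    "rfe",
    "category_enrichment",
]

ALGORITHMS = ("rf", "kknn", "glmnet", "lm", "cubist", "bag", "bstTree", "blackboost")
STRATEGIES = ("by_sample", "by_protein")


@dataclass(frozen=True)
class SplitSpec:
    """How to partition rows into train/test groups."""

    strategy: str = "by_sample"
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class FoldAssignment:
    """Group-level k-fold assignment; rows inherit their group's fold."""

    k: int
    group_to_fold: dict[str, int]
    strategy: str

    def __post_init__(self):
        folds = set(self.group_to_fold.values())
        if folds != set(range(self.k)):
            raise ValueError("every fold must hold at least one group")

    def row_folds(self, keys) -> np.ndarray:
        pos = 0 if self.strategy == "by_protein" else 1
        return np.array([self.group_to_fold[key[pos]] for key in keys])


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm name from the roster plus its hyperparameters."""

    algorithm: str = "rf"
    hyperparameters: tuple = ()   # mapping stored as sorted items for hashability
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; roster: {ALGORITHMS}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(self, "hyperparameters",
                               tuple(sorted(self.hyperparameters.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def _group_ids(keys, strategy: str) -> np.ndarray:
    pos = 0 if strategy == "by_protein" else 1
    return np.array([key[pos] for key in keys])


def group_holdout(keys, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """80/20 (by default) hold-out at the group level.

    The number of training groups is round(train_fraction * n_groups) with
    banker's rounding; all rows of a group stay on the same side.
    """
    ids = _group_ids(keys, spec.strategy)
    groups = sorted(set(ids))
    if len(groups) < 5:
        raise ValueError(f"need at least 5 groups to split, got {len(groups)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(groups))
    n_train = int(round(spec.train_fraction * len(groups)))
    n_train = min(max(n_train, 1), len(groups) - 1)
    train_groups = {groups[i] for i in order[:n_train]}
    in_train = np.isin(ids, sorted(train_groups))
    train_idx = np.flatnonzero(in_train)
    test_idx = np.flatnonzero(~in_train)
    assert not (set(ids[train_idx]) & set(ids[test_idx])), "leaky split"
    return train_idx, test_idx


def group_kfold(keys, strategy: str, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal shuffled groups round-robin into k folds (sizes differ by <= 1)."""
    ids = _group_ids(keys, strategy)
    groups = sorted(set(ids))
    if len(groups) < k:
        raise ValueError(f"need at least k={k} groups, got {len(groups)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    mapping = {groups[g]: i % k for i, g in enumerate(order)}
    return FoldAssignment(k=k, group_to_fold=mapping, strategy=strategy)


# ---------------------------------------------------------------------------
# learner adapters


def _resolve_mtry(value, p: int) -> int:
    if value == "sqrt" or value is None:
        return max(1, int(math.isqrt(p)))
    return int(min(max(1, value), p))


def make_model(spec: ModelSpec, n_features: int, mtry: int | None = None):
    """Instantiate the scikit-learn estimator behind a roster name."""
    hp = spec.params
    seed = spec.seed
    algo = spec.algorithm
    if algo == "rf":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 500),
            max_features=_resolve_mtry(mtry if mtry is not None
                                       else hp.get("mtry", "sqrt"), n_features),
            random_state=seed, n_jobs=hp.get("n_jobs", 1))
    if algo == "kknn":
        return KNeighborsRegressor(n_neighbors=hp.get("k", 7), weights="distance")
    if algo == "glmnet":
        return ElasticNet(alpha=hp.get("alpha", 0.001),
                          l1_ratio=hp.get("l1_ratio", 0.5), max_iter=10000)
    if algo == "lm":
        return LinearRegression()
    if algo == "cubist":
        # committee-of-trees surrogate for rule-based model trees
        return ExtraTreesRegressor(n_estimators=hp.get("n_estimators", 200),
                                   random_state=seed, n_jobs=1)
    if algo == "bag":
        return BaggingRegressor(estimator=DecisionTreeRegressor(),
                                n_estimators=hp.get("n_estimators", 25),
                                random_state=seed)
    if algo == "bstTree":
        return GradientBoostingRegressor(n_estimators=hp.get("n_estimators", 150),
                                         random_state=seed)
    if algo == "blackboost":
        return HistGradientBoostingRegressor(max_iter=hp.get("n_estimators", 150),
                                             random_state=seed)
    raise ValueError(f"unknown algorithm {algo!r}; roster: {ALGORITHMS}")


@dataclass
class ModelBundle:
    """A fitted estimator plus the exact feature list it expects."""

    estimator: object
    features: list[str]
    spec: ModelSpec
    train_rmse: float | None = None
    train_r_squared: float | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.features].to_numpy(dtype=float))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        return joblib.load(path)


def _tune_rf_mtry(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> int:
    """Pick mtry from {2, floor(sqrt p), p-1} by 3-fold CV RMSE."""
    p = X.shape[1]
    grid = sorted({_resolve_mtry(v, p) for v in (2, math.isqrt(p), p - 1)})
    if len(grid) == 1:
        return grid[0]
    kf = KFold(n_splits=3, shuffle=True, random_state=spec.seed)
    best, best_rmse = grid[0], math.inf
    for mtry in grid:
        errs = []
        for tr, te in kf.split(X):
            est = make_model(spec, p, mtry=mtry)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        rmse = float(np.mean(errs))
        if rmse < best_rmse - 1e-12:
            best, best_rmse = mtry, rmse
    return best


def train(spec: ModelSpec, X: pd.DataFrame, y: pd.Series | np.ndarray,
          features: list[str] | None = None) -> ModelBundle:
    """Fit the requested learner on complete rows of the given features.

    For random forests with ``mtry`` unset, mtry is tuned over
    {2, floor(sqrt p), p-1} by inner 3-fold CV RMSE before the final fit.
    """
    if features is None:
        features = list(X.columns)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"features absent from design matrix: {missing[:5]}")
    Xa = X[features].to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("training rows must be complete (no missing values)")
    mtry = None
    if spec.algorithm == "rf" and "mtry" not in spec.params:
        mtry = _tune_rf_mtry(spec, Xa, ya)
    est = make_model(spec, len(features), mtry=mtry)
    est.fit(Xa, ya)
    pred = est.predict(Xa)
    bundle = ModelBundle(estimator=est, features=list(features), spec=spec)
    bundle.train_rmse = float(np.sqrt(np.mean((pred - ya) ** 2)))
    bundle.train_r_squared = _r_squared(pred, ya)
    return bundle


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalMetrics:
    rmse: float
    r_squared: float
    pct_change_vs_train: float | None = None

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r_squared": self.r_squared,
                "pct_change_vs_train": self.pct_change_vs_train}


def _r_squared(pred: np.ndarray, obs: np.ndarray) -> float:
    if len(pred) < 2:
        raise ValueError("r_squared needs at least 2 observations")
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("constant predictions or observations; r_squared set to 0")
        return 0.0
    r, _ = sps.pearsonr(pred, obs)
    return float(r * r)


def evaluate(model: ModelBundle, X: pd.DataFrame, y: pd.Series | np.ndarray
             ) -> EvalMetrics:
    """Held-out RMSE and correlation-form R^2; test rows must be preprocessed
    with the training transform."""
    ya = np.asarray(y, dtype=float)
    if len(ya) < 2:
        raise ValueError("need at least 2 test rows to evaluate")
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((pred - ya) ** 2)))
    metrics = EvalMetrics(rmse=rmse, r_squared=_r_squared(pred, ya))
    if model.train_rmse:
        metrics.pct_change_vs_train = 100.0 * (rmse - model.train_rmse) / model.train_rmse
    return metrics


def importance(model: ModelBundle, X: pd.DataFrame, y: pd.Series | np.ndarray,
               n_repeats: int = 5, seed: int = 0) -> list[tuple[str, float]]:
    """Permutation importance (descending); linear models report |coef|.

    Nearest-neighbour models have no native importance; use the RFE
    aggregated ranking for those.
    """
    if model.spec.algorithm == "kknn":
        raise ValueError("kknn has no native importance; use the RFE ranking")
    est = model.estimator
    if hasattr(est, "coef_"):
        scores = np.abs(np.ravel(est.coef_))
    else:
        result = permutation_importance(
            est, X[model.features].to_numpy(dtype=float),
            np.asarray(y, dtype=float), n_repeats=n_repeats, random_state=seed)
        scores = np.clip(result.importances_mean, 0.0, None)
    pairs = sorted(zip(model.features, scores), key=lambda t: (-t[1], t[0]))
    return [(f, float(s)) for f, s in pairs]


def _native_ranking(est, features: list[str], X: np.ndarray, y: np.ndarray,
                    seed: int) -> list[str]:
    """Feature names sorted best-first by the fitted model's own importance."""
    if hasattr(est, "feature_importances_"):
        scores = est.feature_importances_
    elif hasattr(est, "coef_"):
        scores = np.abs(np.ravel(est.coef_))
    else:
        scores = np.clip(
            permutation_importance(est, X, y, n_repeats=3,
                                   random_state=seed).importances_mean, 0.0, None)
    order = sorted(range(len(features)), key=lambda i: (-scores[i], features[i]))
    return [features[i] for i in order]


@dataclass
class RfeResult:
    """Cross-validated recursive-feature-elimination outcome."""

    per_size: pd.DataFrame            # index: subset size; columns rmse, r_squared
    optimal_size: int
    ranking: list[str]                # aggregated (mean per-fold rank, best first)
    mean_rank: dict[str, float] = field(default_factory=dict)

    def selected_features(self, size: int | None = None) -> list[str]:
        return self.ranking[: (size if size is not None else self.optimal_size)]


def rfe(X: pd.DataFrame, y: pd.Series | np.ndarray, keys, spec: ModelSpec,
        folds: FoldAssignment, sizes: list[int]) -> RfeResult:
    """Recursive feature elimination under group cross-validation.

    Per fold: fit the full model on the fold-training rows, rank features
    by the model's importance, refit on the top-s subset for every
    requested size s, and score the held-out fold.  Per-size metrics are
    averaged over folds; the aggregated ranking is the mean of the
    per-fold ranks (ties broken alphabetically); the optimal size is the
    argmin of mean RMSE (smaller size wins ties).
    """
    features = list(X.columns)
    p = len(features)
    sizes = sorted({int(s) for s in sizes})
    if not sizes or sizes[0] < 1 or sizes[-1] > p:
        raise ValueError(f"sizes must lie within [1, {p}]")
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    row_folds = folds.row_folds(keys)

    rank_sum = np.zeros(p)
    n_folds_used = 0
    per_size_rmse = {s: [] for s in sizes}
    per_size_r2 = {s: [] for s in sizes}
    feat_pos = {f: i for i, f in enumerate(features)}

    for f in range(folds.k):
        tr = row_folds != f
        te = ~tr
        if te.sum() < 2 or np.std(ya[tr]) == 0 or np.std(ya[te]) == 0:
            warnings.warn(f"skipping degenerate fold {f}")
            continue
        full = make_model(spec, p)
        full.fit(Xa[tr], ya[tr])
        ranking = _native_ranking(full, features, Xa[tr], ya[tr], spec.seed)
        for rank, name in enumerate(ranking, start=1):
            rank_sum[feat_pos[name]] += rank
        n_folds_used += 1
        for s in sizes:
            idx = [feat_pos[name] for name in ranking[:s]]
            est = (full if s == p else make_model(spec, s))
            if s != p:
                est.fit(Xa[np.ix_(tr.nonzero()[0], idx)], ya[tr])
            pred = est.predict(Xa[np.ix_(te.nonzero()[0], idx)]) if s != p \
                else full.predict(Xa[te])
            rmse = float(np.sqrt(np.mean((pred - ya[te]) ** 2)))
            per_size_rmse[s].append(rmse)
            per_size_r2[s].append(_r_squared(pred, ya[te]))

    if n_folds_used == 0:
        raise ValueError("all folds degenerate; cannot run RFE")
    per_size = pd.DataFrame({
        "rmse": [float(np.mean(per_size_rmse[s])) for s in sizes],
        "r_squared": [float(np.mean(per_size_r2[s])) for s in sizes],
    }, index=pd.Index(sizes, name="size"))
    optimal_size = int(per_size["rmse"].idxmin())
    mean_rank = rank_sum / n_folds_used
    order = sorted(range(p), key=lambda i: (mean_rank[i], features[i]))
    ranking = [features[i] for i in order]
    return RfeResult(per_size=per_size, optimal_size=optimal_size, ranking=ranking,
                     mean_rank={features[i]: float(mean_rank[i]) for i in order})


def default_rfe_sizes(p: int) -> list[int]:
    """Subset-size grid bracketing both small models and the full feature set."""
    grid = [2, 4, 6, 8, 10, 15, 20, 30, 40, 50, 75, 100]
    return sorted({s for s in grid if s <= p} | {p})


def category_enrichment(selected, category, universe) -> float:
    """One-sided Fisher exact p-value for over-representation of a feature
    category among the selected features."""
    selected, category, universe = set(selected), set(category), set(universe)
    if not selected:
        raise ValueError("selection is empty")
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    k = len(selected & category & universe)
    s = len(selected)
    c = len(category & universe)
    m = len(universe)
    table = [[k, s - k], [c - k, (m - c) - (s - k)]]
    _, p = sps.fisher_exact(table, alternative="greater")
    return float(p)
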