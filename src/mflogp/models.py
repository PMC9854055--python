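"""The six LogP regressors, metrics, tuning, and the factorial experiment.

Six regression families are compared: multivariate linear regression (MLR),
ridge, lasso, random forest (RFR), gradient boosting (GBR) and k-nearest
neighbors (KNNR).  Ridge and lasso penalties follow the un-normalized
objective RSS + lambda * penalty(beta) with an unpenalized intercept; the
lasso is delegated to scikit-learn's coordinate descent with the penalty
rescaled accordingly.  KNN is implemented directly so that ties at the K-th
distance break deterministically toward the lowest training index.

The factorial experiment crosses three binary training-protocol factors --
extended features, cross-validation, tuned hyperparameters -- over all eight
combinations, repeating each with fresh inner 80/20 splits while the outer
test partition stays frozen.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge

from .dataset import CuratedDataset, split_dataset
from .features import WEIGHT_TABLE_VERSION, featurize

MODEL_KINDS = ("mlr", "ridge", "lasso", "rfr", "gbr", "knnr")

#: Sentinel for the lasso reference-toolkit default penalty (per-sample
#: alpha = 1 on standardized features), which over-constrains typical LogP
#: data and zeroes every coefficient.
TOOLKIT_DEFAULT = "toolkit-default"


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameter bundle for one regressor.

    Only the fields relevant to ``kind`` are consulted: ``penalty`` (ridge /
    lasso, in the un-normalized RSS + lambda scale), ``n_estimators`` /
    ``max_depth`` / ``learning_rate`` / ``bootstrap`` (forests and boosting),
    ``n_neighbors`` (KNN).  ``standardize`` z-scores features inside the
    penalized linear fits (never KNN, which works on raw counts).
    """

    kind: str
    extended_features: bool = False
    seed: int = 0
    penalty: float | str | None = None
    standardize: bool = False
    n_estimators: int = 100
    max_depth: int | None = None
    learning_rate: float = 0.1
    bootstrap: bool = True
    n_neighbors: int = 5

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class LinearModelParams:
    """Intercept and coefficient vector of a fitted linear model."""

    intercept: float
    coefficients: np.ndarray


@dataclass
class TrainedModel:
    """An opaque fitted predictor plus the spec that produced it."""

    spec: ModelSpec
    n_features: int
    params: LinearModelParams | None = None
    estimator: object | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)
    knn_data: tuple[np.ndarray, np.ndarray] | None = None  # (X_train, y_train)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


@dataclass
class MetricsReport:
    """RMSE / MAE / R-squared triple (log units; R² dimensionless)."""

    rmse: float
    mae: float
    r2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rmse, self.mae, self.r2], dtype=float)


@dataclass
class ExperimentCell:
    """One factorial combination for one model kind, aggregated over repeats."""

    kind: str
    extra_features: bool
    cross_validation: bool
    tuned_hyperparameters: bool
    repeats: int
    train_mean: MetricsReport
    train_std: MetricsReport
    valid_mean: MetricsReport
    valid_std: MetricsReport
    spec: ModelSpec  # spec used in the final repeat (tuned specs vary by repeat)

    @property
    def factors(self) -> tuple[bool, bool, bool]:
        return (self.extra_features, self.cross_validation, self.tuned_hyperparameters)


def default_spec(kind: str, extended: bool = False, seed: int = 0) -> ModelSpec:
    """Untuned ("base") hyperparameters for each model family.

    These mirror common reference-toolkit defaults: 100 trees / stages,
    unlimited forest depth, boosting depth 3 with learning rate 0.1, K = 5
    neighbors, ridge lambda 1, and the lasso toolkit default (per-sample
    alpha = 1 on standardized features, which over-constrains LogP-scale
    data and zeroes every coefficient).
    """
    base = dict(kind=kind, extended_features=extended, seed=seed)
    if kind == "ridge":
        return ModelSpec(penalty=1.0, standardize=True, **base)
    if kind == "lasso":
        return ModelSpec(penalty=TOOLKIT_DEFAULT, standardize=True, **base)
    if kind == "rfr":
        return ModelSpec(n_estimators=100, max_depth=None, bootstrap=True, **base)
    if kind == "gbr":
        return ModelSpec(n_estimators=100, max_depth=3, learning_rate=0.1, **base)
    if kind == "knnr":
        return ModelSpec(n_neighbors=5, **base)
    return ModelSpec(**base)


# ---------------------------------------------------------------------------
# fitting


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be two-dimensional")
    return X


def _as_vector(y, n_rows: int | None = None) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if n_rows is not None and len(y) != n_rows:
        raise ValueError(f"response length {len(y)} does not match {n_rows} rows")
    return y


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0.0, 1.0, std)
    return mean, std


def fit_mlr(X, y) -> TrainedModel:
    """Ordinary least squares minimizing the residual sum of squares.

    Rank-deficient designs are solved by the minimum-norm least-squares
    solution, with a warning.
    """
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("cannot fit on an empty dataset")
    y = _as_vector(y, X.shape[0])
    design = np.column_stack([np.ones(X.shape[0]), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient design: returning the minimum-norm solution",
            UserWarning,
            stacklevel=2,
        )
    return TrainedModel(
        spec=ModelSpec(kind="mlr"),
        n_features=X.shape[1],
        params=LinearModelParams(intercept=float(beta[0]), coefficients=beta[1:]),
    )


def fit_ridge(X, y, penalty: float, standardize: bool = False) -> TrainedModel:
    """Ridge regression: RSS + penalty * sum(beta^2), intercept unpenalized."""
    if penalty < 0:
        raise ValueError("ridge penalty must be non-negative")
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    scaler = None
    Xf = X
    if standardize:
        scaler = _standardizer(X)
        Xf = (X - scaler[0]) / scaler[1]
    est = Ridge(alpha=penalty, fit_intercept=True)
    est.fit(Xf, y)
    return TrainedModel(
        spec=ModelSpec(kind="ridge", penalty=penalty, standardize=standardize),
        n_features=X.shape[1],
        params=LinearModelParams(intercept=float(est.intercept_), coefficients=est.coef_.copy()),
        scaler=scaler,
    )


def fit_lasso(X, y, penalty: float | str, standardize: bool = False) -> TrainedModel:
    """Lasso regression: RSS + penalty * sum(|beta|), intercept unpenalized.

    ``penalty`` is on the un-normalized RSS scale and is mapped onto
    scikit-learn's per-sample objective via alpha = penalty / (2N).  The
    sentinel :data:`TOOLKIT_DEFAULT` requests the toolkit's own default
    (alpha = 1), i.e. penalty = 2N.  ``penalty = 0`` falls back to the exact
    least-squares solution.
    """
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    n = X.shape[0]
    if penalty == TOOLKIT_DEFAULT:
        alpha = 1.0
    else:
        if penalty < 0:
            raise ValueError("lasso penalty must be non-negative")
        alpha = float(penalty) / (2.0 * n)
    scaler = None
    Xf = X
    if standardize:
        scaler = _standardizer(X)
        Xf = (X - scaler[0]) / scaler[1]
    # a vanishing penalty is least squares to numerical precision; the
    # coordinate-descent solver converges poorly there, so route it to the
    # closed form (shrinkage at alpha < 1e-5 is below solver tolerance)
    if alpha < 1e-5:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            inner = fit_mlr(Xf, y)
        params = inner.params
    else:
        est = Lasso(alpha=alpha, fit_intercept=True, max_iter=10_000, tol=1e-7)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est.fit(Xf, y)
        if any("onverge" in str(w.message) for w in caught):
            warnings.warn(
                f"lasso did not converge within {int(np.max(est.n_iter_))} iterations",
                UserWarning,
                stacklevel=2,
            )
        params = LinearModelParams(intercept=float(est.intercept_), coefficients=est.coef_.copy())
    return TrainedModel(
        spec=ModelSpec(kind="lasso", penalty=penalty, standardize=standardize),
        n_features=X.shape[1],
        params=params,
        scaler=scaler,
    )


def fit_random_forest(X, y, spec: ModelSpec | None = None, seed: int | None = None) -> TrainedModel:
    """Random forest: mean prediction of B bootstrap-resampled trees."""
    spec = spec if spec is not None else default_spec("rfr")
    if seed is not None:
        spec = replace(spec, seed=seed)
    if spec.n_estimators < 1:
        raise ValueError("need at least one tree")
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    est = RandomForestRegressor(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        bootstrap=spec.bootstrap,
        random_state=spec.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return TrainedModel(spec=replace(spec, kind="rfr"), n_features=X.shape[1], estimator=est)


def fit_gbr(X, y, spec: ModelSpec | None = None, seed: int | None = None) -> TrainedModel:
    """Gradient boosting: stagewise sum of shallow trees fit to residuals."""
    spec = spec if spec is not None else default_spec("gbr")
    if seed is not None:
        spec = replace(spec, seed=seed)
    if spec.n_estimators < 1:
        raise ValueError("need at least one boosting stage")
    if spec.learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    est = GradientBoostingRegressor(
        n_estimators=spec.n_estimators,
        learning_rate=spec.learning_rate,
        max_depth=spec.max_depth if spec.max_depth is not None else 3,
        random_state=spec.seed,
    )
    est.fit(X, y)
    return TrainedModel(spec=replace(spec, kind="gbr"), n_features=X.shape[1], estimator=est)


def fit_knn(X, y, n_neighbors: int) -> TrainedModel:
    """K-nearest-neighbor regression on unscaled Euclidean distance.

    Prediction is the unweighted mean response of the K nearest training
    rows; ties at the K-th distance break toward the lowest training index.
    """
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    if not (1 <= n_neighbors <= X.shape[0]):
        raise ValueError(f"n_neighbors must lie in [1, {X.shape[0]}], got {n_neighbors}")
    return TrainedModel(
        spec=ModelSpec(kind="knnr", n_neighbors=n_neighbors),
        n_features=X.shape[1],
        knn_data=(X.copy(), y.copy()),
    )


def fit_from_spec(spec: ModelSpec, X, y) -> TrainedModel:
    """Dispatch a fit according to ``spec.kind``."""
    if spec.kind == "mlr":
        model = fit_mlr(X, y)
    elif spec.kind == "ridge":
        penalty = 1.0 if spec.penalty is None else spec.penalty
        model = fit_ridge(X, y, penalty, standardize=spec.standardize)
    elif spec.kind == "lasso":
        penalty = TOOLKIT_DEFAULT if spec.penalty is None else spec.penalty
        model = fit_lasso(X, y, penalty, standardize=spec.standardize)
    elif spec.kind == "rfr":
        model = fit_random_forest(X, y, spec)
    elif spec.kind == "gbr":
        model = fit_gbr(X, y, spec)
    elif spec.kind == "knnr":
        model = fit_knn(X, y, spec.n_neighbors)
    else:  # pragma: no cover - guarded by ModelSpec.__post_init__
        raise ValueError(f"unknown model kind {spec.kind!r}")
    model.spec = replace(model.spec, extended_features=spec.extended_features, seed=spec.seed)
    return model


# ---------------------------------------------------------------------------
# prediction and metrics


def predict(model: TrainedModel, X) -> np.ndarray:
    """Predict LogP for each row of ``X`` with a fitted model."""
    X = _as_matrix(X)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width mismatch: model expects {model.n_features} columns, got {X.shape[1]}"
        )
    if model.params is not None:
        Xf = X
        if model.scaler is not None:
            Xf = (X - model.scaler[0]) / model.scaler[1]
        return model.params.intercept + Xf @ model.params.coefficients
    if model.estimator is not None:
        return np.asarray(model.estimator.predict(X), dtype=float)
    if model.knn_data is not None:
        X_train, y_train = model.knn_data
        k = model.spec.n_neighbors
        dist = cdist(X, X_train)
        # stable argsort keeps the lowest training index on distance ties
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        return y_train[order].mean(axis=1)
    raise ValueError("model carries no fitted state")  # pragma: no cover


def evaluate(y, yhat) -> MetricsReport:
    """RMSE, MAE and R² of predictions against experimental values.

    R² uses the mean of ``y`` over the evaluated partition; a constant-y
    partition has undefined R² (NaN) unless predictions are exact.
    """
    y = _as_vector(y)
    yhat = _as_vector(yhat)
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} observed vs {len(yhat)} predicted")
    if len(y) < 2:
        raise ValueError("need at least two points to evaluate")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        r2 = 1.0 if sse == 0.0 else float("nan")
    else:
        r2 = 1.0 - sse / sst
    return MetricsReport(rmse=rmse, mae=mae, r2=r2)


# ---------------------------------------------------------------------------
# tuning


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """Exhaustive grid expansion preserving key-insertion / value order."""
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded permutation (deterministic, unstratified)."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, folds)]


def tune(
    kind: str,
    grid: Mapping[str, Sequence],
    X,
    y,
    folds: int = 8,
    seed: int = 0,
    base_spec: ModelSpec | None = None,
) -> ModelSpec:
    """Exhaustive grid search minimizing mean validation RMSE across CV folds.

    Fold assignment is a seeded permutation cut into contiguous blocks; ties
    between grid points break toward the earlier point in grid order.
    """
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    n = X.shape[0]
    if folds < 2:
        raise ValueError("need at least two folds")
    if n < folds:
        raise ValueError(f"cannot run {folds}-fold CV on {n} records")
    base = base_spec if base_spec is not None else default_spec(kind)
    candidates = _expand_grid(grid)
    fold_indices = _cv_folds(n, folds, seed)
    all_idx = np.arange(n)
    best_spec, best_score = None, np.inf
    for cand in candidates:
        spec = replace(base, **cand)
        scores = []
        try:
            for val_idx in fold_indices:
                train_idx = np.setdiff1d(all_idx, val_idx, assume_unique=True)
                model = fit_from_spec(spec, X[train_idx], y[train_idx])
                scores.append(evaluate(y[val_idx], predict(model, X[val_idx])).rmse)
        except ValueError:
            # candidate infeasible at fold size (e.g. K exceeding fold-train N)
            continue
        score = float(np.mean(scores))
        if score < best_score:
            best_spec, best_score = spec, score
    return best_spec


def tune_holdout(
    kind: str,
    grid: Mapping[str, Sequence],
    X,
    y,
    val_fraction: float = 0.2,
    seed: int = 0,
    base_spec: ModelSpec | None = None,
) -> ModelSpec:
    """Grid search against a single random holdout split (no cross-validation)."""
    X = _as_matrix(X)
    y = _as_vector(y, X.shape[0])
    split = split_dataset(X.shape[0], 1.0 - val_fraction, seed)
    tr, va = split.train, split.held_out
    base = base_spec if base_spec is not None else default_spec(kind)
    best_spec, best_score = None, np.inf
    for cand in _expand_grid(grid):
        spec = replace(base, **cand)
        model = fit_from_spec(spec, X[tr], y[tr])
        score = evaluate(y[va], predict(model, X[va])).rmse
        if score < best_score:
            best_spec, best_score = spec, score
    return best_spec


# ---------------------------------------------------------------------------
# factorial experiment


def _cv_training_metrics(spec: ModelSpec, X, y, folds: int, seed: int) -> MetricsReport:
    """Out-of-fold metrics on the training partition under k-fold CV."""
    reports = []
    all_idx = np.arange(X.shape[0])
    for val_idx in _cv_folds(X.shape[0], folds, seed):
        train_idx = np.setdiff1d(all_idx, val_idx, assume_unique=True)
        model = fit_from_spec(spec, X[train_idx], y[train_idx])
        reports.append(evaluate(y[val_idx], predict(model, X[val_idx])).as_array())
    mean = np.mean(reports, axis=0)
    return MetricsReport(*mean)


def _aggregate(reports: list[MetricsReport]) -> tuple[MetricsReport, MetricsReport]:
    arr = np.vstack([r.as_array() for r in reports])
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(3)
    return MetricsReport(*mean), MetricsReport(*std)


def run_factorial(
    ds: CuratedDataset,
    repeats: int = 100,
    seed: int = 0,
    kinds: Sequence[str] = MODEL_KINDS,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    outer_fraction: float = 0.85,
    inner_fraction: float = 0.8,
    folds: int = 8,
) -> list[ExperimentCell]:
    """The 2-level, 3-factor training-protocol experiment.

    Factors: extended features (M = 21 vs 10), 8-fold cross-validation, and
    tuned vs default hyperparameters -- eight cells per model kind.  The
    outer held-out test partition is frozen once from ``seed``; each repeat
    re-randomizes only the inner 80/20 train/validation split, with the same
    per-repeat seeds shared across cells and kinds so cells are paired.
    Reports mean and std of training and validation metrics over repeats.
    """
    from .config import DEFAULT_GRIDS  # local import to avoid a cycle

    if repeats < 1:
        raise ValueError("need at least one repeat")
    grids = grids if grids is not None else DEFAULT_GRIDS
    y = ds.logp
    X_by_flag = {
        False: featurize(ds.counts, extended=False).to_numpy(),
        True: featurize(ds.counts, extended=True).to_numpy(),
    }
    outer = split_dataset(len(ds), outer_fraction, seed)
    pool = outer.train
    cells: list[ExperimentCell] = []
    for extra, cv, tuned in itertools.product([False, True], repeat=3):
        X_pool = X_by_flag[extra][pool]
        y_pool = y[pool]
        for kind in kinds:
            train_reports, valid_reports = [], []
            spec = default_spec(kind, extended=extra)
            for r in range(repeats):
                rs = int(seed + 1009 * (r + 1)) % (2**31)
                inner = split_dataset(len(pool), inner_fraction, rs)
                X_tr, y_tr = X_pool[inner.train], y_pool[inner.train]
                X_va, y_va = X_pool[inner.held_out], y_pool[inner.held_out]
                spec = default_spec(kind, extended=extra, seed=rs)
                grid = grids.get(kind, {})
                if tuned and grid:
                    if cv:
                        spec = tune(kind, grid, X_tr, y_tr, folds=folds, seed=rs, base_spec=spec)
                    else:
                        spec = tune_holdout(kind, grid, X_tr, y_tr, seed=rs, base_spec=spec)
                model = fit_from_spec(spec, X_tr, y_tr)
                if cv and not tuned:
                    train_reports.append(_cv_training_metrics(spec, X_tr, y_tr, folds, rs))
                else:
                    train_reports.append(evaluate(y_tr, predict(model, X_tr)))
                valid_reports.append(evaluate(y_va, predict(model, X_va)))
            t_mean, t_std = _aggregate(train_reports)
            v_mean, v_std = _aggregate(valid_reports)
            cells.append(
                ExperimentCell(
                    kind=kind,
                    extra_features=extra,
                    cross_validation=cv,
                    tuned_hyperparameters=tuned,
                    repeats=repeats,
                    train_mean=t_mean,
                    train_std=t_std,
                    valid_mean=v_mean,
                    valid_std=v_std,
                    spec=spec,
                )
            )
    return cells


def cells_to_frame(cells: Sequence[ExperimentCell]):
    """Flatten experiment cells into a tidy DataFrame (one row per cell/kind)."""
    import pandas as pd

    rows = []
    for c in cells:
        rows.append(
            {
                "kind": c.kind,
                "extra_features": c.extra_features,
                "cross_validation": c.cross_validation,
                "tuned_hyperparameters": c.tuned_hyperparameters,
                "repeats": c.repeats,
                "train_rmse_mean": c.train_mean.rmse,
                "train_rmse_std": c.train_std.rmse,
                "train_mae_mean": c.train_mean.mae,
                "train_mae_std": c.train_std.mae,
                "train_r2_mean": c.train_mean.r2,
                "train_r2_std": c.train_std.r2,
                "valid_rmse_mean": c.valid_mean.rmse,
                "valid_rmse_std": c.valid_std.rmse,
                "valid_mae_mean": c.valid_mean.mae,
                "valid_mae_std": c.valid_std.mae,
                "valid_r2_mean": c.valid_mean.r2,
                "valid_r2_std": c.valid_std.r2,
            }
        )
    return pd.DataFrame(rows)


def select_final(cells: Sequence[ExperimentCell]) -> ModelSpec:
    """Pick the final model spec from completed experiment cells.

    Minimal mean validation RMSE wins outright; any cell within one pooled
    std of the winner competes, and among those the preference is fewer
    features, then fewer training steps (cv/tuning flags off) -- the
    parsimony rule that selects a base 10-feature model over an extended one
    of statistically indistinguishable error.
    """
    if not cells:
        raise ValueError("no experiment cells to select from")
    best = min(cells, key=lambda c: c.valid_mean.rmse)
    contenders = []
    for c in cells:
        pooled = float(np.sqrt((c.valid_std.rmse**2 + best.valid_std.rmse**2) / 2.0))
        if c.valid_mean.rmse - best.valid_mean.rmse <= pooled + 1e-12:
            contenders.append(c)
    contenders.sort(
        key=lambda c: (
            c.extra_features,
            c.cross_validation + c.tuned_hyperparameters,
            c.valid_mean.rmse,
        )
    )
    return contenders[0].spec


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a fitted model with an embedded JSON header.

    The header records the spec, feature width and atomic-weight table
    version so a loaded model can refuse mismatched feature matrices.
    """
    header = {
        "spec": {
            k: (v if not isinstance(v, np.ndarray) else v.tolist())
            for k, v in dataclasses.asdict(model.spec).items()
        },
        "n_features": model.n_features,
        "weight_table": WEIGHT_TABLE_VERSION,
    }
    joblib.dump({"header_json": json.dumps(header), "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return payload["model"]


def model_header(path: str | Path) -> dict:
    """Read back the JSON header of a serialized model."""
    return json.loads(joblib.load(path)["header_json"])
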