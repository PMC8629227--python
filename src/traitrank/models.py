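"""The seven prediction methods benchmarked against each other.

The principal trait is regressed on the ten auxiliary traits with
stepwise multiple regression, a single-hidden-layer perceptron (tanh
hidden units, linear output, L2-regularized quasi-Newton training), a
radial-basis-function network tuned over a neurons x radius grid, and
four tree learners (a single regression tree, bagging, random forest
and gradient boosting).  All fits share the same train/validation split
and report R^2 = 1 - SSE/SST on training, validation and (optionally)
pooled k-fold cross-validation predictions, plus the validation MSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.ensemble import (
    BaggingRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FitResult",
    "RangeScaler",
    "NormalizedRegressor",
    "split_train_validation",
    "kfold_indices",
    "r_squared",
    "normalize_inputs",
    "fit_stepwise",
    "fit_mlp",
    "fit_rbf",
    "fit_tree_ensembles",
]

TREE_METHODS = ("tree", "bagging", "random_forest", "boosting")


def split_train_validation(
    n_or_table, fraction: float = 0.8, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index sets; |train| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError(f"train fraction must be in (0, 1), got {fraction}")
    n = n_or_table if isinstance(n_or_table, (int, np.integer)) else n_or_table.n_individuals
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def kfold_indices(
    n: int, k: int, seed: int | np.random.Generator | None = None
) -> list[np.ndarray]:
    """k disjoint folds partitioning 0..n-1, sizes differing by at most 1."""
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative out of sample)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant; R^2 is undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


class RangeScaler:
    """Columnwise affine map of the training range onto [-1, 1].

    Validation values outside the training range map outside [-1, 1];
    that is intentional (the map is fitted on training data only).
    """

    def __init__(self) -> None:
        self.columns_: list[str] | None = None
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, X: pd.DataFrame) -> "RangeScaler":
        X = pd.DataFrame(X)
        lo, hi = X.min(axis=0).to_numpy(float), X.max(axis=0).to_numpy(float)
        constant = np.flatnonzero(hi == lo)
        if constant.size:
            names = [str(X.columns[i]) for i in constant]
            raise ValueError(f"constant column(s) cannot be range-scaled: {names}")
        self.columns_, self.min_, self.max_ = list(X.columns), lo, hi
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X), dtype=float)
        return 2.0 * (X - self.min_) / (self.max_ - self.min_) - 1.0

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return (Z + 1.0) / 2.0 * (self.max_ - self.min_) + self.min_

    @property
    def midpoint_(self) -> np.ndarray:
        return (self.min_ + self.max_) / 2.0


def normalize_inputs(train: pd.DataFrame) -> tuple[RangeScaler, np.ndarray]:
    """Fit a [-1, 1] range scaler on training data and return it with the
    transformed training matrix."""
    scaler = RangeScaler().fit(train)
    return scaler, scaler.transform(train)


class NormalizedRegressor:
    """Estimator fitted on range-scaled inputs (and optionally a scaled
    response); predictions are returned on the original scale."""

    def __init__(self, estimator, x_scaler: RangeScaler, y_scaler: RangeScaler | None = None):
        self.estimator = estimator
        self.x_scaler = x_scaler
        self.y_scaler = y_scaler

    def predict(self, X) -> np.ndarray:
        return self.predict_normalized(self.x_scaler.transform(X))

    def predict_normalized(self, Z) -> np.ndarray:
        p = np.asarray(self.estimator.predict(np.asarray(Z)), dtype=float).ravel()
        if self.y_scaler is not None:
            p = self.y_scaler.inverse_transform(p.reshape(-1, 1)).ravel()
        return p


@dataclass
class FitResult:
    """One fitted method with its goodness-of-fit diagnostics."""

    method: str
    model: Any
    predictors: list[str]
    r2_train: float
    r2_validation: float
    mse_validation: float
    r2_cv: float = float("nan")
    importance: dict[str, float] = field(default_factory=dict)
    details: dict[str, Any] = field(default_factory=dict)


def _evaluate(
    method: str,
    model,
    predictors: Sequence[str],
    X_train,
    y_train,
    X_val,
    y_val,
    refit: Callable | None = None,
    cv_folds: int | None = None,
    cv_seed: int = 0,
    **extra,
) -> FitResult:
    yhat_tr = model.predict(X_train)
    yhat_val = model.predict(X_val)
    r2_cv = float("nan")
    if cv_folds and refit is not None:
        r2_cv = _cv_r2(refit, X_train, y_train, cv_folds, cv_seed)
    return FitResult(
        method=method,
        model=model,
        predictors=list(predictors),
        r2_train=r_squared(y_train, yhat_tr),
        r2_validation=r_squared(y_val, yhat_val),
        mse_validation=float(np.mean((np.asarray(y_val, float) - yhat_val) ** 2)),
        r2_cv=r2_cv,
        **extra,
    )


def _cv_r2(refit: Callable, X: pd.DataFrame, y, k: int, seed: int) -> float:
    """R^2 of pooled out-of-fold predictions over the training set."""
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    preds = np.empty_like(y)
    for fold in kfold_indices(len(y), k, seed):
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        model = refit(X[mask], y[mask])
        preds[fold] = model.predict(X[~mask])
    return r_squared(y, preds)


# ---------------------------------------------------------------------------
# stepwise multiple regression

class _OLSModel:
    def __init__(self, result, predictors: list[str], fallback_mean: float):
        self.result = result
        self.predictors = predictors
        self.fallback_mean = fallback_mean

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if not self.predictors:
            return np.full(len(X), self.fallback_mean)
        design = sm.add_constant(X[self.predictors].to_numpy(float), has_constant="add")
        return np.asarray(self.result.predict(design), dtype=float)


def _stepwise_select(
    X: pd.DataFrame, y: np.ndarray, p_enter: float, p_remove: float
) -> list[str]:
    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in X.columns if c not in selected]
        if remaining:
            pvals = {}
            for c in remaining:
                design = sm.add_constant(X[selected + [c]].to_numpy(float))
                res = sm.OLS(y, design).fit()
                pvals[c] = res.pvalues[-1]
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        while selected:
            design = sm.add_constant(X[selected].to_numpy(float))
            res = sm.OLS(y, design).fit()
            worst_i = int(np.argmax(res.pvalues[1:]))
            if res.pvalues[1 + worst_i] > p_remove:
                selected.pop(worst_i)
                changed = True
            else:
                break
        if not changed:
            return selected


def fit_stepwise(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    cv_folds: int | None = None,
    cv_seed: int = 0,
) -> FitResult:
    """Bidirectional stepwise OLS; per-predictor |t| is recorded as the
    regression importance measure (0 for traits never selected)."""
    X_train, X_val = pd.DataFrame(X_train), pd.DataFrame(X_val)
    if X_train.shape[1] < 2:
        raise ValueError("stepwise selection needs at least two candidate predictors")
    if len(X_train) <= X_train.shape[1] + 1:
        raise ValueError("too few observations for the number of candidate predictors")
    y_tr = np.asarray(y_train, dtype=float)

    def _fit(X: pd.DataFrame, y: np.ndarray) -> _OLSModel:
        sel = _stepwise_select(X, y, p_enter, p_remove)
        if sel:
            design = sm.add_constant(X[sel].to_numpy(float))
            res = sm.OLS(y, design).fit()
        else:
            res = None
        return _OLSModel(res, sel, float(np.mean(y)))

    model = _fit(X_train, y_tr)
    importance = {c: 0.0 for c in X_train.columns}
    if model.predictors:
        tvals = model.result.tvalues[1:]
        for c, t in zip(model.predictors, tvals):
            importance[c] = float(abs(t))
    return _evaluate(
        "stepwise", model, model.predictors, X_train, y_tr, X_val, y_val,
        refit=_fit, cv_folds=cv_folds, cv_seed=cv_seed,
        importance=importance,
        details={"coefficients": None if model.result is None else model.result.params},
    )


# ---------------------------------------------------------------------------
# multilayer perceptron

def fit_mlp(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    hidden_neurons: int = 30,
    max_epochs: int = 5000,
    mse_stop: float = 1e-3,
    alpha: float = 1.0,
    seed: int = 0,
    cv_folds: int | None = None,
    cv_seed: int = 0,
) -> FitResult:
    """Single-hidden-layer perceptron: tanh hidden units, linear output.

    Inputs and response are range-scaled to [-1, 1] on the training set.
    Training is L2-regularized quasi-Newton (LBFGS), run in bursts until
    the training MSE (on the scaled response) drops to ``mse_stop`` or
    ``max_epochs`` iterations have been spent.  The default weight decay
    is deliberately strong (alpha = 1), in the spirit of
    Bayesian-regularized backpropagation: with n_train in the hundreds a
    30-unit tanh network memorizes the noise otherwise.
    """
    X_train, X_val = pd.DataFrame(X_train), pd.DataFrame(X_val)
    y_tr = np.asarray(y_train, dtype=float)

    def _fit(X: pd.DataFrame, y: np.ndarray) -> NormalizedRegressor:
        x_scaler, Z = normalize_inputs(X)
        y_scaler = RangeScaler().fit(pd.DataFrame({"y": y}))
        t = y_scaler.transform(pd.DataFrame({"y": y})).ravel()
        est = MLPRegressor(
            hidden_layer_sizes=(hidden_neurons,),
            activation="tanh",
            solver="lbfgs",
            alpha=alpha,
            max_iter=1,
            tol=0.0,
            warm_start=True,
            random_state=seed,
        )
        burst, spent = 200, 0
        while spent < max_epochs:
            est.max_iter = min(burst, max_epochs - spent)
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Z, t)
            spent += est.max_iter
            mse = float(np.mean((est.predict(Z) - t) ** 2))
            if not np.isfinite(mse):
                raise FloatingPointError("MLP training produced a non-finite loss")
            if mse <= mse_stop:
                break
        return NormalizedRegressor(est, x_scaler, y_scaler)

    model = _fit(X_train, y_tr)
    est = model.estimator
    return _evaluate(
        "mlp", model, list(X_train.columns), X_train, y_tr, X_val, y_val,
        refit=_fit, cv_folds=cv_folds, cv_seed=cv_seed,
        details={
            "weights_input_hidden": est.coefs_[0],
            "weights_hidden_output": est.coefs_[1],
            "hidden_neurons": hidden_neurons,
        },
    )


# ---------------------------------------------------------------------------
# radial basis function network

class RBFNetwork:
    """Gaussian RBF units at k-means centers with least-squares output weights."""

    def __init__(self, centers: np.ndarray, radius: float, coef: np.ndarray):
        self.centers = centers
        self.radius = radius
        self.coef = coef

    def _design(self, Z: np.ndarray) -> np.ndarray:
        phi = np.exp(-cdist(Z, self.centers, "sqeuclidean") / (2.0 * self.radius**2))
        return np.column_stack([np.ones(len(Z)), phi])

    def predict(self, Z) -> np.ndarray:
        return self._design(np.asarray(Z, dtype=float)) @ self.coef

    @classmethod
    def fit(cls, Z: np.ndarray, y: np.ndarray, centers: np.ndarray, radius: float) -> "RBFNetwork":
        stub = cls(centers, radius, None)
        phi = stub._design(Z)
        # tiny ridge keeps the solve stable when units saturate at large radius
        gram = phi.T @ phi + 1e-8 * np.eye(phi.shape[1])
        stub.coef = np.linalg.solve(gram, phi.T @ y)
        return stub


def fit_rbf(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    neurons: Sequence[int] = tuple(range(10, 31, 2)),
    radii: Sequence[float] = tuple(np.arange(5.0, 15.0 + 0.25, 0.5)),
    seed: int = 0,
    cv_folds: int | None = None,
    cv_seed: int = 0,
) -> FitResult:
    """Grid search over (number of centers, Gaussian radius); the cell with
    the highest validation R^2 wins.  Defaults scan 11 x 21 = 231 cells."""
    X_train, X_val = pd.DataFrame(X_train), pd.DataFrame(X_val)
    y_tr = np.asarray(y_train, dtype=float)
    y_v = np.asarray(y_val, dtype=float)
    if max(neurons) > len(X_train):
        raise ValueError("more RBF centers requested than training points")

    x_scaler, Z_train = normalize_inputs(X_train)
    Z_val = x_scaler.transform(X_val)

    best = None
    for k in neurons:
        km = KMeans(n_clusters=int(k), random_state=seed, n_init=4).fit(Z_train)
        for radius in radii:
            net = RBFNetwork.fit(Z_train, y_tr, km.cluster_centers_, float(radius))
            r2v = r_squared(y_v, net.predict(Z_val))
            if best is None or r2v > best[0]:
                best = (r2v, int(k), float(radius), net)
    _, k_best, radius_best, net = best
    model = NormalizedRegressor(net, x_scaler)

    def _refit(X: pd.DataFrame, y: np.ndarray) -> NormalizedRegressor:
        xs, Z = normalize_inputs(X)
        km = KMeans(n_clusters=k_best, random_state=seed, n_init=4).fit(Z)
        return NormalizedRegressor(
            RBFNetwork.fit(Z, np.asarray(y, float), km.cluster_centers_, radius_best), xs
        )

    return _evaluate(
        "rbf", model, list(X_train.columns), X_train, y_tr, X_val, y_val,
        refit=_refit, cv_folds=cv_folds, cv_seed=cv_seed,
        details={"neurons": k_best, "radius": radius_best},
    )


# ---------------------------------------------------------------------------
# tree ensembles

def _make_tree_estimator(method: str, n_trees: int, seed: int):
    if method == "tree":
        return DecisionTreeRegressor(random_state=seed)
    if method == "bagging":
        # bootstrap resampling, every predictor available at every split
        return BaggingRegressor(
            DecisionTreeRegressor(), n_estimators=n_trees, random_state=seed
        )
    if method == "random_forest":
        # regression-forest convention: a third of the predictors per split
        return RandomForestRegressor(
            n_estimators=n_trees, max_features=1.0 / 3.0, random_state=seed
        )
    if method == "boosting":
        return GradientBoostingRegressor(
            n_estimators=n_trees, max_depth=3, learning_rate=0.1, random_state=seed
        )
    raise ValueError(f"unknown tree method {method!r}; expected one of {TREE_METHODS}")


class _ArrayModel:
    """Adapter so tree estimators accept DataFrames without column checks."""

    def __init__(self, estimator):
        self.estimator = estimator

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)), dtype=float)


def fit_tree_ensembles(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    method: str = "random_forest",
    n_trees: int = 5000,
    seed: int = 0,
    cv_folds: int | None = None,
    cv_seed: int = 0,
) -> FitResult:
    """Fit one of: single regression tree, bagged trees, random forest, or
    gradient boosting (squared error, depth-3 trees, shrinkage 0.1)."""
    X_train, X_val = pd.DataFrame(X_train), pd.DataFrame(X_val)
    y_tr = np.asarray(y_train, dtype=float)

    def _fit(X: pd.DataFrame, y: np.ndarray) -> _ArrayModel:
        est = _make_tree_estimator(method, n_trees, seed)
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return _ArrayModel(est)

    model = _fit(X_train, y_tr)
    return _evaluate(
        method, model, list(X_train.columns), X_train, y_tr, X_val, y_val,
        refit=_fit, cv_folds=cv_folds, cv_seed=cv_seed,
        details={"n_trees": n_trees},
    )
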