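"""Variable-importance measures for the fitted prediction methods.

Four families of measures are implemented:

* Garson/Goh connection-weight partitioning for the perceptron —
  absolute input-to-hidden weights are partitioned per hidden unit,
  weighted by the absolute hidden-to-output weight, and normalized to
  percentages summing to 100;
* permutation drop in R^2 (pVR): the validation R^2 minus the mean R^2
  after shuffling one predictor column;
* zero-input destructuring: validation R^2 after holding one predictor
  at the center of its normalized [-1, 1] range;
* permutation rise in MSE (IV and %IMSE) for the tree learners.

All permutation measures shuffle a single column of the validation set,
average over ``n_perm`` independent permutations, and leave the fitted
model untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import FitResult, NormalizedRegressor, r_squared

__all__ = [
    "garson_importance",
    "perm_importance_r2",
    "zero_importance_r2",
    "imse_importance",
    "importance_report",
    "rank_scores",
]


def garson_importance(
    weights_input_hidden: np.ndarray,
    weights_hidden_output: np.ndarray,
    input_names=None,
) -> pd.Series:
    """Relative contribution (%) of each input of a single-hidden-layer
    network, by Garson's weight partitioning with Goh's absolute-value
    treatment.  Bias terms are excluded; scores sum to 100.
    """
    W = np.abs(np.asarray(weights_input_hidden, dtype=float))  # (n_inputs, n_hidden)
    v = np.abs(np.asarray(weights_hidden_output, dtype=float)).reshape(-1)  # (n_hidden,)
    if W.ndim != 2 or W.shape[1] != v.shape[0]:
        raise ValueError("weight shapes do not describe a single hidden layer")
    col_sums = W.sum(axis=0)
    active = col_sums > 0  # hidden units with no input connections carry nothing
    Q = (W[:, active] / col_sums[active]) @ v[active]
    total = Q.sum()
    if total == 0:
        raise ValueError("all connection weights are zero; contributions undefined")
    scores = 100.0 * Q / total
    if input_names is None:
        input_names = [f"x{i + 1}" for i in range(W.shape[0])]
    return pd.Series(scores, index=list(input_names), name="garson")


def _as_matrix(X) -> tuple[np.ndarray, list]:
    X = pd.DataFrame(X)
    return X.to_numpy(dtype=float), list(X.columns)


def _column_index(columns: list, trait) -> int:
    if trait in columns:
        return columns.index(trait)
    if isinstance(trait, (int, np.integer)) and 0 <= trait < len(columns):
        return int(trait)
    raise KeyError(f"unknown predictor {trait!r}")


def perm_importance_r2(
    model, X_val, y_val, trait, n_perm: int = 10, seed: int | np.random.Generator | None = None
) -> float:
    """pVR: observed validation R^2 minus the mean R^2 over ``n_perm``
    permutations of the given predictor column.  Larger = more important."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xm, cols = _as_matrix(X_val)
    j = _column_index(cols, trait)
    y = np.asarray(y_val, dtype=float)
    r2_obs = r_squared(y, model.predict(Xm if not cols else pd.DataFrame(Xm, columns=cols)))
    # average the per-permutation drops (not the permuted R^2 values) so an
    # ignored column yields exactly 0 rather than accumulated rounding noise
    drops = np.empty(n_perm)
    Xp = Xm.copy()
    for p in range(n_perm):
        Xp[:, j] = Xm[rng.permutation(len(Xm)), j]
        drops[p] = r2_obs - r_squared(y, model.predict(pd.DataFrame(Xp, columns=cols)))
    return float(drops.mean())


def zero_importance_r2(model: NormalizedRegressor, X_val, y_val, trait) -> float:
    """Validation R^2 after holding one predictor constant at 0 on the
    normalized [-1, 1] scale (the center of its training range)."""
    if not isinstance(model, NormalizedRegressor):
        raise TypeError("zero-input destructuring requires a model fitted on normalized inputs")
    Xm, cols = _as_matrix(X_val)
    j = _column_index(cols, trait)
    Z = model.x_scaler.transform(pd.DataFrame(Xm, columns=cols))
    Z[:, j] = 0.0
    return r_squared(np.asarray(y_val, dtype=float), model.predict_normalized(Z))


def imse_importance(
    model, X_val, y_val, trait, n_perm: int = 10, seed: int | np.random.Generator | None = None
) -> tuple[float, float]:
    """(IV, %IMSE): mean rise in validation MSE when one predictor is
    shuffled, and that rise as a percentage of the baseline MSE."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xm, cols = _as_matrix(X_val)
    j = _column_index(cols, trait)
    y = np.asarray(y_val, dtype=float)
    mse_base = float(np.mean((y - model.predict(pd.DataFrame(Xm, columns=cols))) ** 2))
    if mse_base == 0:
        raise ValueError("baseline MSE is zero; %IMSE is undefined")
    rises = np.empty(n_perm)
    Xp = Xm.copy()
    for p in range(n_perm):
        Xp[:, j] = Xm[rng.permutation(len(Xm)), j]
        rises[p] = np.mean((y - model.predict(pd.DataFrame(Xp, columns=cols))) ** 2) - mse_base
    iv = float(rises.mean())
    return iv, 100.0 * iv / mse_base


def _batched_perm_predictions(
    model, X_val: pd.DataFrame, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Predictions after shuffling each column in turn, all permutations
    stacked into a single model.predict call.

    Returns an array of shape (n_cols, n_perm, n_val).  Batching matters
    for the tree ensembles, where per-call prediction overhead dominates.
    """
    Xm, cols = _as_matrix(X_val)
    n = len(Xm)
    blocks = []
    for j in range(Xm.shape[1]):
        for _ in range(n_perm):
            Xp = Xm.copy()
            Xp[:, j] = Xm[rng.permutation(n), j]
            blocks.append(Xp)
    stacked = pd.DataFrame(np.vstack(blocks), columns=cols)
    preds = np.asarray(model.predict(stacked), dtype=float)
    return preds.reshape(Xm.shape[1], n_perm, n)


def rank_scores(scores: pd.Series, larger_is_better: bool = True) -> pd.Series:
    """Importance ranks (1 = most important); average rank on ties."""
    return scores.rank(ascending=not larger_is_better, method="average")


def importance_report(
    fit: FitResult,
    X_val: pd.DataFrame,
    y_val,
    n_perm: int = 10,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """All importance measures applicable to one fitted method, tidy.

    Columns: method, measure, trait, score, rank.  For the perceptron the
    Garson partitioning, pVR and zero-input R^2 are reported; for the RBF
    network pVR and zero-input R^2; for stepwise the |t| statistics and
    pVR; for the tree learners IV and %IMSE.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X_val = pd.DataFrame(X_val)
    traits = list(X_val.columns)
    blocks: list[pd.DataFrame] = []

    def _block(measure: str, scores: pd.Series, larger_is_better: bool = True) -> None:
        blocks.append(
            pd.DataFrame(
                {
                    "method": fit.method,
                    "measure": measure,
                    "trait": scores.index,
                    "score": scores.to_numpy(float),
                    "rank": rank_scores(scores, larger_is_better).to_numpy(float),
                }
            )
        )

    if fit.method == "mlp":
        _block(
            "garson",
            garson_importance(
                fit.details["weights_input_hidden"],
                fit.details["weights_hidden_output"],
                traits,
            ),
        )
    if fit.method == "stepwise":
        _block("t_statistic", pd.Series({t: fit.importance.get(t, 0.0) for t in traits}))
    y = np.asarray(y_val, dtype=float)
    if fit.method in ("stepwise", "mlp", "rbf"):
        preds = _batched_perm_predictions(fit.model, X_val, n_perm, rng)
        r2_obs = r_squared(y, fit.model.predict(X_val))
        sst = np.sum((y - y.mean()) ** 2)
        r2_perm = 1.0 - np.sum((preds - y) ** 2, axis=2) / sst  # (n_traits, n_perm)
        _block("perm_r2", pd.Series((r2_obs - r2_perm).mean(axis=1), index=traits))
    if fit.method in ("mlp", "rbf"):
        # R^2 after zeroing: the *drop* ranks the trait, so smaller R^2 = more important
        zr = pd.Series({t: zero_importance_r2(fit.model, X_val, y_val, t) for t in traits})
        _block("zero_r2", zr, larger_is_better=False)
    if fit.method in ("tree", "bagging", "random_forest", "boosting"):
        preds = _batched_perm_predictions(fit.model, X_val, n_perm, rng)
        mse_base = float(np.mean((y - fit.model.predict(X_val)) ** 2))
        if mse_base == 0:
            raise ValueError("baseline MSE is zero; %IMSE is undefined")
        iv = (np.mean((preds - y) ** 2, axis=2) - mse_base).mean(axis=1)
        _block("perm_mse", pd.Series(iv, index=traits))
        _block("pct_imse", pd.Series(100.0 * iv / mse_base, index=traits))
    return pd.concat(blocks, ignore_index=True)
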