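"""Random-forest fitting with out-of-bag (OOB) permutation importance.

The importances computed here are the classical R-`randomForest` quantities:

* classification — *MeanDecreaseAccuracy*: for each feature, the drop in a
  tree's OOB accuracy when that feature's values are permuted among the OOB
  samples, averaged over trees;
* regression — *%IncMSE*: the increase in a tree's OOB mean squared error
  under the same per-feature permutation, averaged over trees and expressed
  as a percent of the mean per-tree OOB MSE.

scikit-learn provides the tree ensembles but not OOB permutation importance
(its ``permutation_importance`` uses a held-out set, not per-tree bag masks),
so the importance computation is implemented here on top of each tree's
bootstrap mask.  Impurity-based importance is deliberately not used: it
ranks features differently and is not what "mean decrease accuracy" means.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["ForestConfig", "ImportanceTable", "fit_classifier", "fit_regressor"]

# R randomForest nodesize defaults are 1 (classification) and 5 (regression),
# meaning: a node with more than nodesize samples may still be split and its
# children may be arbitrarily small.  The sklearn equivalent is
# min_samples_split = nodesize + 1 with min_samples_leaf = 1 — NOT
# min_samples_leaf = nodesize, which would forbid most splits at n ~ 20 and
# degrade the trees to stumps.
_MIN_SPLIT = {"classification": 2, "regression": 6}
_MTRY_RULES = ("sqrt_p", "p_over_3")


@dataclass(frozen=True)
class ForestConfig:
    """Hyper-parameters of one forest fit.

    Parameters
    ----------
    ntree
        Number of trees. The study-scale values are 16,000 (classification)
        and 4,000 (regression); the default here is a computationally
        lighter 500, which is ample for n = 20 cohorts.
    features_per_split
        Candidate features per split: an integer, one of the rules
        ``"sqrt_p"`` / ``"p_over_3"``, or None for the mode default
        (``sqrt_p`` in classification, ``p_over_3`` in regression —
        the R randomForest defaults).
    seed
        Seeds both the forest construction and the importance permutations.
    importance_scaled
        If True, divide each mean decrease by its standard error across
        trees (R's ``scale=TRUE``). Default False: raw mean decrease.
    """

    ntree: int = 500
    features_per_split: int | str | None = None
    seed: int = 0
    importance_scaled: bool = False

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError(f"ntree must be >= 1, got {self.ntree}")
        f = self.features_per_split
        if f is not None and not (
            (isinstance(f, (int, np.integer)) and f >= 1) or f in _MTRY_RULES
        ):
            raise ValueError(
                f"features_per_split must be a positive int, one of {_MTRY_RULES}, "
                f"or None, got {f!r}"
            )

    def resolve_mtry(self, n_features: int, mode: str) -> int:
        f = self.features_per_split
        if f is None:
            f = "sqrt_p" if mode == "classification" else "p_over_3"
        if f == "sqrt_p":
            return max(1, int(math.floor(math.sqrt(n_features))))
        if f == "p_over_3":
            return max(1, n_features // 3)
        return int(f)


@dataclass(frozen=True)
class ImportanceTable:
    """Per-feature importance values with a deterministic ordering.

    ``values`` is indexed by feature identifier; ``mode`` records whether the
    numbers are MeanDecreaseAccuracy (classification) or %IncMSE
    (regression). Ties in importance are broken by feature identifier so
    every ranking derived from the table is reproducible.
    """

    values: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown importance mode {self.mode!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("importance values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    def ordered(self) -> pd.Series:
        """Importances sorted descending, equal values sorted by feature id."""
        df = self.values.rename("importance").rename_axis("feature_id").reset_index()
        df["feature_id"] = df["feature_id"].astype(str)
        df = df.sort_values(
            ["importance", "feature_id"], ascending=[False, True], kind="mergesort"
        )
        return df.set_index("feature_id")["importance"]

    def to_frame(self) -> pd.DataFrame:
        """Exportable table with columns feature_id, importance, rank (1 = best)."""
        ordered = self.ordered()
        return pd.DataFrame(
            {
                "feature_id": ordered.index,
                "importance": ordered.to_numpy(),
                "rank": np.arange(1, len(ordered) + 1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    return arr, [f"f{j}" for j in range(arr.shape[1])]


def _oob_index_lists(model, n_samples: int) -> list[np.ndarray]:
    """Out-of-bag sample indices for every tree of a fitted forest."""
    assert model.max_samples is None  # bootstrap size == n_samples throughout
    out = []
    for est in model.estimators_:
        # replicates sklearn's _generate_sample_indices for unweighted bootstrap
        rs = np.random.RandomState(est.random_state)
        in_bag = rs.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[in_bag] = False
        out.append(np.flatnonzero(mask))
    return out


def _permutation_rng(cfg: ForestConfig) -> np.random.Generator:
    # independent of the stream sklearn consumes for tree construction
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 0x0BB])


def _oob_permutation_importance(
    model, X: np.ndarray, y: np.ndarray, cfg: ForestConfig, mode: str
) -> np.ndarray:
    """Mean per-tree OOB loss increase under per-feature permutation.

    Returns MeanDecreaseAccuracy (classification) or %IncMSE (regression).
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    rng = _permutation_rng(cfg)
    sum_delta = np.zeros(p)
    sumsq_delta = np.zeros(p)
    base_loss_sum = 0.0
    n_used = 0
    if mode == "classification":
        y_enc = np.searchsorted(model.classes_, y)
    for est, oob in zip(model.estimators_, _oob_index_lists(model, n)):
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X32[oob].copy()
        if mode == "classification":
            truth = y_enc[oob]
            pred = est.predict(Xo, check_input=False)
            base = np.mean(pred != truth)  # error rate
        else:
            truth = y[oob]
            pred = est.predict(Xo, check_input=False)
            base = np.mean((pred - truth) ** 2)
        base_loss_sum += base
        m = len(oob)
        for j in range(p):
            col = Xo[:, j].copy()
            Xo[:, j] = col[rng.permutation(m)]
            pred = est.predict(Xo, check_input=False)
            if mode == "classification":
                loss = np.mean(pred != truth)
            else:
                loss = np.mean((pred - truth) ** 2)
            Xo[:, j] = col
            delta = loss - base
            sum_delta[j] += delta
            sumsq_delta[j] += delta * delta
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples; increase ntree")
    mean_delta = sum_delta / n_used
    if cfg.importance_scaled:
        var = sumsq_delta / n_used - mean_delta**2
        se = np.sqrt(np.maximum(var, 0.0) / n_used)
        return np.where(se > 0, mean_delta / se, 0.0)
    if mode == "classification":
        # permuted error minus baseline error == decrease in accuracy
        return mean_delta
    mean_base_mse = base_loss_sum / n_used
    if mean_base_mse == 0:
        raise ValueError("OOB MSE is zero; response carries no residual variance")
    return 100.0 * mean_delta / mean_base_mse


def _validate_X_y(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN or infinite values")
    if X.shape[0] != len(y):
        raise ValueError(
            f"X has {X.shape[0]} rows but y has {len(y)} entries"
        )


def fit_classifier(X, y, cfg: ForestConfig, compute_importance: bool = True):
    """Fit a classification forest; return (model, ImportanceTable).

    The ImportanceTable holds OOB permutation MeanDecreaseAccuracy.  With
    ``compute_importance=False`` (used inside cross-validation loops where
    only predictions are needed) the second element is None.
    """
    Xm, feature_ids = _as_matrix(X)
    y_arr = np.asarray(pd.Series(y).to_numpy())
    _validate_X_y(Xm, y_arr)
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise ValueError("classification requires at least 2 classes in y")
    model = RandomForestClassifier(
        n_estimators=cfg.ntree,
        max_features=cfg.resolve_mtry(Xm.shape[1], "classification"),
        min_samples_split=_MIN_SPLIT["classification"],
        bootstrap=True,
        random_state=int(cfg.seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    model.fit(Xm, y_arr)
    if not compute_importance:
        return model, None
    imp = _oob_permutation_importance(model, Xm, y_arr, cfg, "classification")
    table = ImportanceTable(
        values=pd.Series(imp, index=feature_ids, name="MeanDecreaseAccuracy"),
        mode="classification",
    )
    return model, table


def fit_regressor(X, y, cfg: ForestConfig, compute_importance: bool = True):
    """Fit a regression forest; return (model, ImportanceTable of %IncMSE)."""
    Xm, feature_ids = _as_matrix(X)
    y_arr = np.asarray(pd.Series(y).to_numpy(), dtype=float)
    _validate_X_y(Xm, y_arr)
    if not np.all(np.isfinite(y_arr)):
        raise ValueError("y contains NaN or infinite values")
    if np.ptp(y_arr) == 0:
        raise ValueError("y is constant; OOB MSE contrast is undefined")
    model = RandomForestRegressor(
        n_estimators=cfg.ntree,
        max_features=cfg.resolve_mtry(Xm.shape[1], "regression"),
        min_samples_split=_MIN_SPLIT["regression"],
        bootstrap=True,
        random_state=int(cfg.seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    model.fit(Xm, y_arr)
    if not compute_importance:
        return model, None
    imp = _oob_permutation_importance(model, Xm, y_arr, cfg, "regression")
    table = ImportanceTable(
        values=pd.Series(imp, index=feature_ids, name="%IncMSE"),
        mode="regression",
    )
    return model, table


def with_seed(cfg: ForestConfig, seed: int) -> ForestConfig:
    """Copy of ``cfg`` with a different seed (convenience for CV loops)."""
    return dataclasses.replace(cfg, seed=int(seed) & 0x7FFFFFFF)
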