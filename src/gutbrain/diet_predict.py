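"""Diet classification: LOOCV, importance-based selection, nested CV.

Two accuracy estimates are first-class and deliberately different:

* :func:`loocv` after :func:`select_top_features` on an all-data importance
  fit reproduces the optimistic headline procedure (feature selection sees
  every sample, so the leave-one-out estimate is inflated);
* :func:`nested_cv` repeats stratified k-fold CV with the importance
  ranking and top-k selection re-run inside every training split, giving an
  honest estimate of out-of-sample accuracy.

With four balanced diet classes a random classifier scores 25%; both
reports should be read against that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest_engine import ForestConfig, ImportanceTable, fit_classifier, with_seed

__all__ = [
    "CvReport",
    "loocv",
    "select_top_features",
    "nested_cv",
    "chance_accuracy",
    "monte_carlo_chance_accuracy",
]


@dataclass(frozen=True)
class CvReport:
    """Cross-validation outcome.

    ``accuracy`` is pooled (confusion-matrix trace over grand total). For
    repeated CV, ``fold_accuracies`` holds every repeat x fold accuracy and
    ``ci_halfwidth`` the half-width of the normal-approximation 95% interval
    around their mean.
    """

    predictions: pd.Series
    confusion: pd.DataFrame  # true class (rows) x predicted class (columns)
    accuracy: float
    fold_accuracies: tuple = ()
    mean_accuracy: float | None = None
    sd_accuracy: float | None = None
    ci_halfwidth: float | None = None

    def __post_init__(self) -> None:
        total = int(self.confusion.to_numpy().sum())
        if total != len(self.predictions):
            raise ValueError("confusion-matrix grand total must equal #predictions")
        trace = float(np.trace(self.confusion.to_numpy()))
        if total and abs(self.accuracy - trace / total) > 1e-12:
            raise ValueError("accuracy must equal confusion trace / grand total")

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.confusion.iterrows()
            },
        }
        if self.fold_accuracies:
            out.update(
                fold_accuracies=list(self.fold_accuracies),
                mean_accuracy=self.mean_accuracy,
                sd_accuracy=self.sd_accuracy,
                ci_halfwidth=self.ci_halfwidth,
            )
        return out


def _confusion(y_true: pd.Series, y_pred: pd.Series, classes) -> pd.DataFrame:
    cm = pd.crosstab(y_true, y_pred)
    return cm.reindex(index=classes, columns=classes, fill_value=0)


def _classes_of(y: pd.Series, classes=None):
    return tuple(classes) if classes is not None else tuple(sorted(set(y)))


def loocv(X: pd.DataFrame, y: pd.Series, cfg: ForestConfig, classes=None) -> CvReport:
    """Leave-one-out CV: each sample predicted by a forest fit on the rest."""
    y = pd.Series(y)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    classes = _classes_of(y, classes)
    fold_seeds = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 0x100]).integers(
        0, 2**31 - 1, size=n
    )
    preds = {}
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y.iloc[train]
        if y_tr.nunique() < 2:
            raise ValueError(
                f"training fold leaving out sample {y.index[i]!r} has a single class"
            )
        model, _ = fit_classifier(
            X.iloc[train], y_tr, with_seed(cfg, fold_seeds[i]), compute_importance=False
        )
        preds[y.index[i]] = model.predict(
            X.iloc[[i]].to_numpy(dtype=float)
        )[0]
    predictions = pd.Series(preds).loc[y.index]
    cm = _confusion(y, predictions, classes)
    total = cm.to_numpy().sum()
    return CvReport(
        predictions=predictions,
        confusion=cm,
        accuracy=float(np.trace(cm.to_numpy()) / total),
    )


def select_top_features(imp: ImportanceTable, k: int) -> list:
    """The k most important features; ties broken stably by feature id."""
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k > len(imp):
        raise ValueError(f"k={k} exceeds the {len(imp)} available features")
    return list(imp.ordered().index[:k])


def stratified_fold_assignment(
    y: pd.Series, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per sample: per class, shuffle then deal round-robin.

    With c classes of exactly `folds` members each, every fold receives one
    sample of every class.
    """
    y = pd.Series(y)
    counts = y.value_counts()
    if folds > counts.min():
        raise ValueError(
            f"{folds}-fold stratification infeasible: smallest class has "
            f"{counts.min()} samples"
        )
    assign = np.empty(len(y), dtype=int)
    pos = {lab: i for i, lab in enumerate(y.index)}
    for cls in sorted(counts.index):
        members = [pos[i] for i in y.index[y == cls]]
        order = rng.permutation(len(members))
        for slot, m in enumerate(order):
            assign[members[m]] = slot % folds
    return assign


def nested_cv(
    X: pd.DataFrame,
    y: pd.Series,
    k: int,
    cfg: ForestConfig,
    folds: int = 5,
    repeats: int = 3,
    sem_interval: bool = False,
    classes=None,
) -> CvReport:
    """Repeated stratified k-fold CV with selection inside every training split.

    Per training split: fit a forest with OOB permutation importance, keep
    the top-``k`` features, refit on those features only, and predict the
    held-out fold. No held-out sample ever influences its own feature
    selection. The 95% interval half-width is 1.96 x the sample sd of the
    repeat x fold accuracies (or 1.96 x sd/sqrt(#folds) with
    ``sem_interval=True``).
    """
    y = pd.Series(y)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    classes = _classes_of(y, classes)
    master = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 0x200])
    fold_acc = []
    all_preds = {}
    for r in range(repeats):
        assign = stratified_fold_assignment(y, folds, master)
        fit_seeds = master.integers(0, 2**31 - 1, size=(folds, 2))
        for f in range(folds):
            test = assign == f
            train = ~test
            y_tr = y.iloc[train]
            if y_tr.nunique() < 2:
                raise ValueError(f"training split of repeat {r}, fold {f} has one class")
            _, imp = fit_classifier(X.iloc[train], y_tr, with_seed(cfg, fit_seeds[f, 0]))
            selected = select_top_features(imp, k)
            model, _ = fit_classifier(
                X.iloc[train][selected],
                y_tr,
                with_seed(cfg, fit_seeds[f, 1]),
                compute_importance=False,
            )
            pred = model.predict(X.iloc[test][selected].to_numpy(dtype=float))
            truth = y.iloc[test]
            fold_acc.append(float(np.mean(pred == truth.to_numpy())))
            for sid, p in zip(truth.index, pred):
                all_preds[(r, sid)] = (truth.loc[sid], p)
    truth_series = pd.Series({key: t for key, (t, _) in all_preds.items()})
    pred_series = pd.Series({key: p for key, (_, p) in all_preds.items()})
    cm = _confusion(truth_series, pred_series, classes)
    total = cm.to_numpy().sum()
    acc = np.asarray(fold_acc)
    sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
    half = 1.96 * (sd / np.sqrt(len(acc)) if sem_interval else sd)
    return CvReport(
        predictions=pred_series,
        confusion=cm,
        accuracy=float(np.trace(cm.to_numpy()) / total),
        fold_accuracies=tuple(acc),
        mean_accuracy=float(acc.mean()),
        sd_accuracy=sd,
        ci_halfwidth=float(half),
    )


def chance_accuracy(n_classes: int = 4) -> float:
    """Expected accuracy of a uniform random classifier on balanced classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


def monte_carlo_chance_accuracy(
    n_classes: int = 4, draws: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo check of the chance baseline with `draws` random predictions."""
    rng = np.random.default_rng(seed)
    truth = np.arange(draws) % n_classes
    pred = rng.integers(0, n_classes, size=draws)
    return float(np.mean(truth == pred))
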