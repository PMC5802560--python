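"""Rank-product scoring that links OTUs to brain features.

Three importance rankings feed the score of an (OTU i, brain feature j)
pair:

* ``S(OTU_i)``      — rank of OTU i's MeanDecreaseAccuracy for predicting
  diet, over the N_OTU OTUs;
* ``S(BrainM_j)``   — rank of feature j's MeanDecreaseAccuracy for
  predicting diet, over the N_BrainM brain features;
* ``S(OTU_i, BrainM_j)`` — rank of OTU i's %IncMSE in the regression forest
  that predicts feature j from all OTUs, over the N_OTU OTUs of that
  regression.

Each rank is ascending (most important feature gets rank N) and divided by
N, so scores live in (0, 1] with ties averaged.  The combined score is the
product of the three; pairs are ordered by it, the top pairs feed three
downstream diet classifiers (OTU-only, brain-only, both) grown by forward
selection, and a score cutoff (0.84 in the emulated analysis) extracts the
confident pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .forest_engine import ForestConfig, ImportanceTable, fit_classifier, fit_regressor, with_seed
from .diet_predict import CvReport, loocv
from .preprocess import BrainFeatureTable, DietLabels, OtuTable

__all__ = [
    "RankScore",
    "rank_score",
    "score_all_pairs",
    "select_top_pairs",
    "forward_select",
    "apply_threshold",
    "score_cohort",
    "write_circos_links",
    "PAIR_COLUMNS",
]

PAIR_COLUMNS = ["otu_id", "brain_feature_id", "s_otu", "s_brain", "s_pair", "s_combined"]


@dataclass(frozen=True)
class RankScore:
    """Rank-derived scores in (0, 1]: score = ascending rank / N."""

    scores: pd.Series
    n: int

    def __post_init__(self) -> None:
        if len(self.scores) != self.n:
            raise ValueError("RankScore length disagrees with N")


def rank_score(imp: ImportanceTable) -> RankScore:
    """Score every feature by its ascending importance rank over N.

    The most important feature gets N/N = 1; the least important 1/N; tied
    importances share the average of their rank positions, which preserves
    the exact rank-sum N(N+1)/2.
    """
    vals = imp.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("importance table contains NaN")
    n = len(vals)
    if n == 0:
        raise ValueError("importance table is empty")
    ranks = rankdata(vals, method="average")
    return RankScore(scores=pd.Series(ranks / n, index=imp.values.index, name="score"), n=n)


def score_all_pairs(
    otu_imp_for_diet: ImportanceTable,
    brain_imp_for_diet: ImportanceTable,
    per_brain_regressions: dict,
) -> pd.DataFrame:
    """Score every (OTU, brain feature) pair; one row per pair.

    ``per_brain_regressions`` maps each brain feature id to the
    %IncMSE ImportanceTable of the regression predicting that feature from
    all OTUs.  Rows are ordered by descending ``s_combined``, ties broken
    by (otu_id, brain_feature_id).
    """
    otu_ids = list(otu_imp_for_diet.values.index)
    brain_ids = list(brain_imp_for_diet.values.index)
    missing = set(brain_ids) - set(per_brain_regressions)
    if missing:
        raise ValueError(f"regression map lacks brain features: {sorted(missing)}")
    s_otu = rank_score(otu_imp_for_diet).scores
    s_brain = rank_score(brain_imp_for_diet).scores
    frames = []
    for bf in brain_ids:
        reg = per_brain_regressions[bf]
        if set(reg.values.index) != set(otu_ids):
            raise ValueError(
                f"regression for brain feature {bf!r} ranks a different OTU universe"
            )
        s_pair = rank_score(reg).scores.reindex(otu_ids)
        frames.append(
            pd.DataFrame(
                {
                    "otu_id": otu_ids,
                    "brain_feature_id": bf,
                    "s_otu": s_otu.reindex(otu_ids).to_numpy(),
                    "s_brain": s_brain[bf],
                    "s_pair": s_pair.to_numpy(),
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs["s_combined"] = pairs["s_otu"] * pairs["s_brain"] * pairs["s_pair"]
    pairs = pairs.sort_values(
        ["s_combined", "otu_id", "brain_feature_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return pairs[PAIR_COLUMNS]


def select_top_pairs(pairs: pd.DataFrame, k: int = 27) -> pd.DataFrame:
    """First k pairs of the deterministic s_combined ordering."""
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} scored pairs")
    return pairs.head(k).reset_index(drop=True)


def apply_threshold(pairs: pd.DataFrame, cutoff: float = 0.84) -> pd.DataFrame:
    """Pairs with s_combined >= cutoff, order preserved (may be empty)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    return pairs[pairs["s_combined"] >= cutoff].reset_index(drop=True)


@dataclass(frozen=True)
class ForwardSelectionResult:
    selected: pd.DataFrame  # the pair prefix that was accepted
    report: CvReport  # LOOCV report of the final feature set
    reached: bool  # whether target_accuracy was attained
    accuracies: tuple  # LOOCV accuracy after each added pair


def _pair_features(pairs: pd.DataFrame, mode: str) -> list:
    feats: list = []
    for _, row in pairs.iterrows():
        cols = []
        if mode in ("otu", "both"):
            cols.append(("otu", row["otu_id"]))
        if mode in ("brain", "both"):
            cols.append(("brain", row["brain_feature_id"]))
        for c in cols:
            if c not in feats:
                feats.append(c)
    return feats


def forward_select(
    pairs: pd.DataFrame,
    otu_values: pd.DataFrame,
    brain_values: pd.DataFrame,
    y,
    cfg: ForestConfig,
    target_accuracy: float = 1.0,
    mode: str = "both",
) -> ForwardSelectionResult:
    """Add pairs in s_combined order until diet LOOCV reaches the target.

    ``mode`` picks which of the three downstream models is grown: the
    OTU-only, brain-only, or combined feature set of the accepted pairs.
    If the target is never reached, all pairs are consumed and
    ``reached`` is False.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to select from")
    if not (0.0 < target_accuracy <= 1.0):
        raise ValueError(f"target_accuracy must lie in (0, 1], got {target_accuracy}")
    if mode not in ("otu", "brain", "both"):
        raise ValueError(f"mode must be otu|brain|both, got {mode!r}")
    y = pd.Series(y)
    accuracies = []
    report = None
    n_selected = 0
    for m in range(1, len(pairs) + 1):
        feats = _pair_features(pairs.head(m), mode)
        cols = []
        for kind, name in feats:
            src = otu_values if kind == "otu" else brain_values
            cols.append(src[name].rename(f"{kind}:{name}"))
        X = pd.concat(cols, axis=1).loc[y.index]
        report = loocv(X, y, cfg)
        accuracies.append(report.accuracy)
        n_selected = m
        if report.accuracy >= target_accuracy:
            break
    reached = accuracies[-1] >= target_accuracy
    return ForwardSelectionResult(
        selected=pairs.head(n_selected).reset_index(drop=True),
        report=report,
        reached=reached,
        accuracies=tuple(accuracies),
    )


@dataclass(frozen=True)
class PairScoreResult:
    pairs: pd.DataFrame
    otu_importance: ImportanceTable
    brain_importance: ImportanceTable
    regressions: dict  # brain feature id -> ImportanceTable over OTUs


def score_cohort(
    otu: OtuTable,
    brain: BrainFeatureTable,
    labels: DietLabels,
    cfg_classification: ForestConfig,
    cfg_regression: ForestConfig,
) -> PairScoreResult:
    """Run the full scoring stage on a preprocessed, aligned cohort.

    Fits the two diet classifiers (OTU features; brain features) and one
    regression forest per brain feature (all OTUs as predictors), then
    combines the three rank scores for every pair. Requires the prescribed
    scales: log2 OTUs and z-scaled brain features.
    """
    if otu.scale != "log2":
        raise ValueError("OTU table must be log2-transformed before scoring")
    if brain.scale != "zscaled":
        raise ValueError("brain table must be z-scaled before scoring")
    if not (otu.sample_ids == brain.sample_ids == labels.sample_ids):
        raise ValueError("tables are not aligned; run preprocess.align_cohort first")
    y = labels.labels
    _, otu_imp = fit_classifier(otu.values, y, cfg_classification)
    _, brain_imp = fit_classifier(brain.values, y, cfg_classification)
    reg_seeds = np.random.default_rng(
        [int(cfg_regression.seed) & 0x7FFFFFFF, 0x300]
    ).integers(0, 2**31 - 1, size=len(brain.feature_ids))
    regressions = {}
    for s, bf in zip(reg_seeds, brain.feature_ids):
        _, imp = fit_regressor(otu.values, brain.values[bf], with_seed(cfg_regression, s))
        regressions[bf] = imp
    pairs = score_all_pairs(otu_imp, brain_imp, regressions)
    return PairScoreResult(
        pairs=pairs,
        otu_importance=otu_imp,
        brain_importance=brain_imp,
        regressions=regressions,
    )


def write_circos_links(pairs: pd.DataFrame, path) -> None:
    """Tab-separated link table (otu_id, brain_feature_id, s_combined)."""
    pairs[["otu_id", "brain_feature_id", "s_combined"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
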