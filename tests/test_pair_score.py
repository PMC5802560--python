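"""Rank-product pair scoring: rank scores, enumeration oracle, selection."""

import numpy as np
import pandas as pd
import pytest
from helpers import make_imp
from hypothesis import given
from hypothesis import strategies as st

from gutbrain import ForestConfig
from gutbrain.pair_score import (
    apply_threshold,
    forward_select,
    rank_score,
    score_all_pairs,
    score_cohort,
    select_top_pairs,
)


class TestRankScore:
    def test_three_feature_example(self):
        rs = rank_score(make_imp({"a": 0.9, "b": 0.2, "c": 0.5}))
        assert rs.scores.to_dict() == pytest.approx({"a": 1.0, "b": 1 / 3, "c": 2 / 3})

    def test_single_feature_scores_one(self):
        assert rank_score(make_imp({"a": -2.0})).scores.to_dict() == {"a": 1.0}

    def test_ties_share_average_rank(self):
        rs = rank_score(make_imp({"a": 0.5, "b": 0.5}))
        assert rs.scores.to_dict() == pytest.approx({"a": 0.75, "b": 0.75})

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rank_score(make_imp({"a": np.nan, "b": 1.0}))

    @given(st.lists(st.sampled_from([-1.5, -0.2, 0.0, 0.3, 0.7, 2.0]), min_size=1, max_size=12))
    def test_score_sum_conserved_under_any_tie_configuration(self, vals):
        n = len(vals)
        rs = rank_score(make_imp({f"f{i:02d}": v for i, v in enumerate(vals)}))
        assert rs.scores.sum() == pytest.approx((n + 1) / 2)
        assert rs.scores.min() >= 1 / n - 1e-12
        assert rs.scores.max() <= 1.0 + 1e-12

    @given(st.permutations(list(range(8))))
    def test_tie_free_vector_spans_full_range(self, perm):
        rs = rank_score(make_imp({f"f{i}": float(v) for i, v in enumerate(perm)}))
        assert rs.scores.max() == 1.0
        assert rs.scores.min() == pytest.approx(1 / 8)


def brute_force_pairs(otu_imp: dict, brain_imp: dict, regressions: dict) -> list:
    """Independent enumeration oracle for score_all_pairs."""

    def ranks(d):
        vals = sorted(d.values())
        return {
            k: (1 + sum(v > x for x in vals) + sum(v >= x for x in vals)) / 2
            for k, v in d.items()
        }

    s_otu = {k: r / len(otu_imp) for k, r in ranks(otu_imp).items()}
    s_brain = {k: r / len(brain_imp) for k, r in ranks(brain_imp).items()}
    out = []
    for bf, reg in regressions.items():
        s_pair = {k: r / len(reg) for k, r in ranks(reg).items()}
        for otu in otu_imp:
            out.append(
                (otu, bf, s_otu[otu], s_brain[bf], s_pair[otu],
                 s_otu[otu] * s_brain[bf] * s_pair[otu])
            )
    return sorted(out, key=lambda r: (-r[5], r[0], r[1]))


class TestScoreAllPairs:
    otu_imp = {"o1": 3.0, "o2": 1.0, "o3": 2.0}
    brain_imp = {"b1": 0.4, "b2": 0.9}
    regs = {
        "b1": {"o1": 5.0, "o2": 1.0, "o3": 3.0},
        "b2": {"o1": 0.1, "o2": 0.9, "o3": 0.5},
    }

    def scored(self):
        return score_all_pairs(
            make_imp(self.otu_imp),
            make_imp(self.brain_imp),
            {bf: make_imp(r, mode="regression") for bf, r in self.regs.items()},
        )

    def test_matches_enumeration_oracle(self):
        got = self.scored()
        expected = brute_force_pairs(self.otu_imp, self.brain_imp, self.regs)
        assert len(got) == len(expected) == 6
        for row, exp in zip(got.itertuples(index=False), expected):
            assert (row.otu_id, row.brain_feature_id) == exp[:2]
            assert row.s_otu == pytest.approx(exp[2])
            assert row.s_brain == pytest.approx(exp[3])
            assert row.s_pair == pytest.approx(exp[4])
            assert row.s_combined == pytest.approx(exp[5])

    def test_combined_is_exact_product_and_bounded(self):
        got = self.scored()
        np.testing.assert_array_equal(
            got["s_combined"], got["s_otu"] * got["s_brain"] * got["s_pair"]
        )
        assert (got["s_combined"] > 0).all() and (got["s_combined"] <= 1).all()
        # top score 1 iff top-ranked in all three lists
        top = got.iloc[0]
        assert (top["s_combined"] == 1.0) == (
            top["s_otu"] == top["s_brain"] == top["s_pair"] == 1.0
        )

    def test_top_in_all_three_scores_one(self):
        got = score_all_pairs(
            make_imp({"o1": 2.0, "o2": 1.0}),
            make_imp({"b1": 2.0, "b2": 1.0}),
            {
                "b1": make_imp({"o1": 2.0, "o2": 1.0}, mode="regression"),
                "b2": make_imp({"o1": 2.0, "o2": 1.0}, mode="regression"),
            },
        )
        assert got.iloc[0]["s_combined"] == 1.0
        assert (got.iloc[0]["otu_id"], got.iloc[0]["brain_feature_id"]) == ("o1", "b1")

    def test_component_rank_improvement_never_lowers_combined(self):
        base = self.scored().set_index(["otu_id", "brain_feature_id"])
        better_regs = {k: dict(v) for k, v in self.regs.items()}
        better_regs["b1"]["o2"] = 10.0  # o2 rises to top of b1's regression
        improved = score_all_pairs(
            make_imp(self.otu_imp),
            make_imp(self.brain_imp),
            {bf: make_imp(r, mode="regression") for bf, r in better_regs.items()},
        ).set_index(["otu_id", "brain_feature_id"])
        assert improved.loc[("o2", "b1"), "s_combined"] >= base.loc[("o2", "b1"), "s_combined"]

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            score_all_pairs(
                make_imp(self.otu_imp),
                make_imp(self.brain_imp),
                {
                    "b1": make_imp({"o1": 1.0}, mode="regression"),
                    "b2": make_imp(self.regs["b2"], mode="regression"),
                },
            )
        with pytest.raises(ValueError, match="lacks"):
            score_all_pairs(
                make_imp(self.otu_imp),
                make_imp(self.brain_imp),
                {"b1": make_imp(self.regs["b1"], mode="regression")},
            )


class TestSelection:
    def pairs(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "otu_id": [f"o{i}" for i in range(n)],
                "brain_feature_id": "b1",
                "s_otu": rng.uniform(size=n),
                "s_brain": 1.0,
                "s_pair": 1.0,
            }
        )
        df["s_combined"] = df["s_otu"]
        return df.sort_values("s_combined", ascending=False).reset_index(drop=True)

    def test_top_pairs_non_increasing(self):
        top = select_top_pairs(self.pairs(), 27)
        assert len(top) == 27
        assert (np.diff(top["s_combined"]) <= 0).all()
        full = select_top_pairs(self.pairs(), 40)
        pd.testing.assert_frame_equal(full, self.pairs())

    @pytest.mark.parametrize("k", [0, -3, 41])
    def test_bad_k_rejected(self, k):
        with pytest.raises(ValueError):
            select_top_pairs(self.pairs(), k)

    def test_threshold_filters_inclusively(self):
        df = self.pairs(5)
        df["s_combined"] = [1.0, 0.9, 0.84, 0.83, 0.1]
        assert len(apply_threshold(df, 0.84)) == 3
        assert len(apply_threshold(df, 0.0)) == 5
        assert list(apply_threshold(df, 1.0)["s_combined"]) == [1.0]
        with pytest.raises(ValueError, match="cutoff"):
            apply_threshold(df, 1.5)


class TestForwardSelect:
    def single_predictor_tables(self):
        """One OTU whose value alone encodes the diet."""
        idx = [f"s{i:02d}" for i in range(20)]
        y = pd.Series(np.repeat(list("ABCD"), 5), index=idx)
        rng = np.random.default_rng(0)
        otu = pd.DataFrame(
            {
                "o_key": np.repeat([0.0, 5.0, 10.0, 15.0], 5) + rng.normal(0, 0.1, 20),
                "o_noise": rng.normal(size=20),
            },
            index=idx,
        )
        brain = pd.DataFrame({"roi01:fa": rng.normal(size=20)}, index=idx)
        pairs = pd.DataFrame(
            {
                "otu_id": ["o_key", "o_noise"],
                "brain_feature_id": ["roi01:fa", "roi01:fa"],
                "s_otu": [1.0, 0.5],
                "s_brain": [1.0, 1.0],
                "s_pair": [1.0, 0.5],
                "s_combined": [1.0, 0.25],
            }
        )
        return pairs, otu, brain, y

    def test_perfect_predictor_stops_after_one_pair(self):
        pairs, otu, brain, y = self.single_predictor_tables()
        res = forward_select(pairs, otu, brain, y, ForestConfig(ntree=60, seed=1),
                             mode="otu")
        assert res.reached
        assert len(res.selected) == 1
        assert res.report.accuracy == 1.0

    def test_uninformative_pairs_never_reach_target(self):
        idx = [f"s{i:02d}" for i in range(20)]
        rng = np.random.default_rng(3)
        y = pd.Series(np.repeat(list("ABCD"), 5), index=idx)
        otu = pd.DataFrame(rng.normal(size=(20, 2)), index=idx, columns=["o1", "o2"])
        brain = pd.DataFrame(rng.normal(size=(20, 2)), index=idx,
                             columns=["roi01:fa", "roi01:rd"])
        pairs = pd.DataFrame(
            {
                "otu_id": ["o1", "o2", "o1", "o2"],
                "brain_feature_id": ["roi01:fa", "roi01:fa", "roi01:rd", "roi01:rd"],
                "s_otu": 0.5, "s_brain": 0.5, "s_pair": 0.5, "s_combined": 0.125,
            }
        )
        res = forward_select(pairs, otu, brain, y, ForestConfig(ntree=60, seed=1))
        assert not res.reached
        assert len(res.selected) == len(pairs)

    def test_invalid_target_rejected(self):
        pairs, otu, brain, y = self.single_predictor_tables()
        with pytest.raises(ValueError, match="target_accuracy"):
            forward_select(pairs, otu, brain, y, ForestConfig(ntree=5),
                           target_accuracy=0.0)


class TestScoreCohortGuards:
    def test_requires_prescribed_scales(self, strong_cohort):
        cfg = ForestConfig(ntree=5)
        with pytest.raises(ValueError, match="log2"):
            score_cohort(strong_cohort.otu, strong_cohort.brain,
                         strong_cohort.labels, cfg, cfg)
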