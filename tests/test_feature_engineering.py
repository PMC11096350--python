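import numpy as np
import pandas as pd
import pytest

from hrvpc.errors import PipelineError, ValidationError
from hrvpc.feature_engineering import (gamma_rank, minmax_scale,
                                       prune_collinear, rank_features,
                                       screen_univariate, select_top)
from hrvpc.protocol import CohortTable, FEATURE_COLUMNS


def _cohort(frame_values: dict, groups) -> CohortTable:
    n = len(groups)
    rng = np.random.default_rng(55)
    frame = pd.DataFrame({c: rng.normal(size=n) for c in FEATURE_COLUMNS},
                         index=[f"s{i}" for i in range(n)])
    for col, vals in frame_values.items():
        frame[col] = vals
    frame["group"] = groups
    return CohortTable(frame)


def _groups(n1=30, n2=30):
    return ["dcSSc"] * n1 + ["lcSSc"] * n2


class TestScreening:
    def test_informative_kept_constant_excluded(self):
        rng = np.random.default_rng(8)
        effect = np.concatenate([rng.normal(5, 1, 30), rng.normal(0, 1, 30)])
        flat = np.concatenate([np.linspace(0, 1, 30)] * 2)
        t = _cohort({"mean_HR_S2": effect, "sd_RR_S1": flat}, _groups())
        kept = screen_univariate(t)
        assert "mean_HR_S2" in kept
        assert "sd_RR_S1" not in kept

    def test_planted_features_recovered(self, synthetic_cohort):
        kept = screen_univariate(synthetic_cohort)
        # the preset plants strong group effects in HR and the delta metrics
        assert "mean_HR_S2" in kept and "SD2_delta" in kept

    def test_empty_survivor_set_errors(self):
        t = _cohort({}, _groups(5, 5))
        # alpha so strict nothing survives pure-noise screening
        with pytest.raises(PipelineError):
            screen_univariate(t, alpha=1e-12)


class TestPruning:
    def test_duplicated_column_removed_once(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=60)
        t = _cohort({"SD1_S1": x, "RMSSD_S1": x}, _groups())
        kept, log = prune_collinear(t, ["SD1_S1", "RMSSD_S1", "CorDim_S2"])
        assert len(kept) == 2 and "CorDim_S2" in kept
        assert len(log) == 1 and log[0]["r2"] == pytest.approx(1.0)

    def test_orthogonal_untouched(self):
        t = _cohort({}, _groups())
        feats = ["mean_HR_S1", "SD2_S2", "CorDim_delta"]
        kept, log = prune_collinear(t, feats)
        assert kept == feats and log == []

    def test_sd1_rmssd_identity_forces_removal(self, synthetic_cohort):
        kept, log = prune_collinear(synthetic_cohort, ["SD1_S1", "RMSSD_S1"])
        assert len(kept) == 1
        assert log[0]["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_row_order_independent(self, synthetic_cohort):
        feats = ["SD1_S1", "RMSSD_S1", "SD2_S1", "sd_RR_S1", "mean_HR_S1"]
        kept1, _ = prune_collinear(synthetic_cohort, feats)
        shuffled = CohortTable(synthetic_cohort.frame.sample(
            frac=1, random_state=1))
        kept2, _ = prune_collinear(shuffled, feats)
        assert kept1 == kept2


class TestScaling:
    def test_maps_to_unit_interval(self, synthetic_cohort):
        scaled, kept = minmax_scale(synthetic_cohort,
                                    ["mean_HR_S1", "SD2_delta"])
        assert scaled.min().min() == 0.0 and scaled.max().max() == 1.0

    def test_constant_feature_dropped_with_warning(self):
        t = _cohort({"NN50_S1": np.full(60, 7.0)}, _groups())
        with pytest.warns(UserWarning, match="constant"):
            _, kept = minmax_scale(t, ["NN50_S1", "mean_HR_S1"])
        assert kept == ["mean_HR_S1"]


class TestRanking:
    def test_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        effect = np.concatenate([rng.normal(4, 1, 30), rng.normal(0, 1, 30)])
        t = _cohort({"CorDim_delta": effect}, _groups())
        feats = ["CorDim_delta", "mean_RR_S1", "SD2_S1", "ApEn_S2", "Lmax_S1"]
        table = rank_features(t, feats, seed=0)
        assert table.index[0] == "CorDim_delta"
        assert table.loc["CorDim_delta", "final_rank"] == 1

    def test_redundancy_score_definition(self, synthetic_cohort):
        feats = ["mean_HR_S2", "SD2_delta", "CorDim_delta", "sd_HR_delta"]
        table = rank_features(synthetic_cohort, feats, seed=1)
        ranks = table[[f"rank_{i}" for i in range(1, 6)]]
        assert np.allclose(table["redundancy_score"],
                           ranks.mean(axis=1) + ranks.std(axis=1, ddof=1))
        # every selector emits a permutation of 1..n
        for col in ranks:
            assert sorted(ranks[col]) == list(range(1, len(feats) + 1))

    def test_deterministic_at_fixed_seed(self, synthetic_cohort):
        feats = ["mean_HR_S2", "SD2_delta", "CorDim_delta", "sd_HR_delta"]
        a = rank_features(synthetic_cohort, feats, seed=2)
        b = rank_features(synthetic_cohort, feats, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_delta_features_dominate_on_preset_cohort(self, synthetic_cohort):
        kept = screen_univariate(synthetic_cohort)
        pruned, _ = prune_collinear(synthetic_cohort, kept)
        table = rank_features(synthetic_cohort, pruned, seed=3)
        top5 = list(table.index[:5])
        assert sum(f.endswith("_delta") or f.endswith("_S2")
                   for f in top5) >= 3


class TestGammaRank:
    def test_identical_distributions_near_zero(self):
        t = _cohort({}, _groups())
        g = gamma_rank(t, ["mean_RR_S1"])
        assert g["mean_RR_S1"] < 0.5

    def test_closed_form_separation(self):
        rng = np.random.default_rng(11)
        a = rng.normal(3, 1, 4000)
        b = rng.normal(0, 1, 4000)
        t = _cohort({"SD2_delta": np.concatenate([a, b])},
                    _groups(4000, 4000))
        g = gamma_rank(t, ["SD2_delta"])
        assert g["SD2_delta"] == pytest.approx(3 / np.sqrt(2), rel=0.05)

    def test_translation_invariance(self, synthetic_cohort):
        g1 = gamma_rank(synthetic_cohort, ["mean_HR_S2"])
        shifted = CohortTable(synthetic_cohort.frame.assign(
            mean_HR_S2=synthetic_cohort.frame["mean_HR_S2"] + 1000))
        g2 = gamma_rank(shifted, ["mean_HR_S2"])
        assert g1["mean_HR_S2"] == pytest.approx(g2["mean_HR_S2"], rel=1e-9)


class TestSelectTop:
    @staticmethod
    def _rank_table(order):
        return pd.DataFrame({"final_rank": range(1, len(order) + 1)},
                            index=order)

    def test_identical_rankings(self):
        names = list("abcde") + ["f", "g"]
        rt = self._rank_table(names)
        gt = pd.Series(np.linspace(2, 0.1, len(names)), index=names)
        sel, info = select_top(rt, gt, n_top=5)
        assert sel == names[:5]
        assert info["arbiter_filled"] == []

    def test_disjoint_lists_arbiter_fills(self):
        rt = self._rank_table(list("abcdefghij"))
        gt = pd.Series(np.linspace(2, 0.1, 10), index=list("jihgfedcba"))
        sel, info = select_top(rt, gt, n_top=3)
        assert len(sel) == 3
        assert len(info["arbiter_filled"]) == 3

    def test_four_of_five_agreement_with_expert_override(self):
        rt = self._rank_table(["SD2_delta", "sd_HR_delta", "CorDim_delta",
                               "SD2_S2", "LF_power_S2", "mean_HR_S2"])
        gt = pd.Series([6, 5, 4, 3, 2, 1],
                       index=["SD2_delta", "sd_HR_delta", "CorDim_delta",
                              "SD2_S2", "mean_HR_S2", "LF_power_S2"])
        sel, info = select_top(rt, gt, n_top=5, arbiter=["mean_HR_S2"])
        assert len(info["agreed"]) == 4
        assert sel[-1] == "mean_HR_S2"

    def test_too_many_requested(self):
        rt = self._rank_table(list("ab"))
        with pytest.raises(ValidationError):
            select_top(rt, pd.Series([1, 2], index=list("ab")), n_top=5)
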