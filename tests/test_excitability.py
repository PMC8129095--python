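"""Classification rule and group statistics, with independent ANOVA oracles."""

import numpy as np
import pandas as pd
import pytest

from lfpexcite import (classify_cohort, classify_slice, high_spike_threshold,
                       mixed_anova, proportion_table, shapiro_gate, tukey_hsd,
                       two_group_test)
from lfpexcite.excitability import HIGH_SPIKES, INTERICTAL, NO_ABNORMAL


class TestHighSpikeThreshold:
    @pytest.mark.parametrize("counts, expected", [
        ([5, 5, 5], 5.0),
        ([0, 10], 5.0 + 2.0 * np.std([0, 10], ddof=1)),   # 19.1421356...
        ([3, 3, 9, 9], 6.0 + 2.0 * np.std([3, 3, 9, 9], ddof=1)),  # 12.9282...
    ])
    def test_mean_plus_two_sample_sds(self, counts, expected):
        assert high_spike_threshold(counts) == pytest.approx(expected, abs=1e-12)

    def test_hand_values(self):
        assert high_spike_threshold([0, 10]) == pytest.approx(19.14213562373095, abs=1e-12)
        assert high_spike_threshold([3, 3, 9, 9]) == pytest.approx(12.928203230275509, abs=1e-12)

    def test_single_count_rejected(self):
        with pytest.raises(ValueError):
            high_spike_threshold([5])


class TestClassifySlice:
    def test_any_iid_wins(self):
        assert classify_slice(2, 0, 15.0) == INTERICTAL
        assert classify_slice(1, 100, 15.0) == INTERICTAL

    def test_strictly_more_spikes_than_threshold(self):
        assert classify_slice(0, 16, 15.0) == HIGH_SPIKES
        assert classify_slice(0, 15, 15.0) == NO_ABNORMAL

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_slice(-1, 0, 15.0)


class TestProportions:
    def test_proportions_sum_to_one(self):
        df = pd.DataFrame({
            "genotype": ["KO"] * 16 + ["WT"] * 16,
            "ka_nm": [150.0] * 32,
            "spike_count": [20] * 6 + [5] * 10 + [5] * 16,
            "iid_count": [1] * 6 + [0] * 10 + [0] * 16,
        })
        classified = classify_cohort(df)
        props = proportion_table(classified)
        ko = props[props.genotype == "KO"].iloc[0]
        assert ko[INTERICTAL] == pytest.approx(6 / 16)  # 0.375, as printed
        sums = props[[INTERICTAL, HIGH_SPIKES, NO_ABNORMAL]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_all_quiet_cohort(self):
        df = pd.DataFrame({"genotype": ["WT"] * 4, "ka_nm": [150.0] * 4,
                           "spike_count": [3, 3, 3, 3], "iid_count": [0] * 4})
        props = proportion_table(classify_cohort(df))
        assert props.iloc[0][NO_ABNORMAL] == 1.0


class TestShapiroGate:
    def test_gaussian_usually_normal(self):
        rng = np.random.default_rng(0)
        calls = [shapiro_gate(rng.normal(size=50)) for _ in range(100)]
        assert 0.88 <= np.mean([c == "normal" for c in calls]) <= 1.0

    def test_lognormal_flagged(self):
        rng = np.random.default_rng(1)
        calls = [shapiro_gate(np.exp(rng.normal(size=50))) for _ in range(20)]
        assert np.mean([c == "non_normal" for c in calls]) >= 0.9

    def test_constant_routed_non_normal(self):
        assert shapiro_gate([2.0, 2.0, 2.0, 2.0]) == "non_normal"

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])


def balanced_table(seed=0, n_subj=4, effect=0.0):
    """Balanced 2 (genotype) x 3 (level) design, n_subj subjects per group."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, genotype in enumerate(("WT", "KO")):
        for s in range(n_subj):
            subj_eff = rng.normal(0, 0.5)
            for li, level in enumerate((50.0, 150.0, 400.0)):
                rows.append({
                    "genotype": genotype, "ka_nm": level,
                    "slice_id": f"{genotype}{s}",
                    "dv": rng.normal(0, 1) + subj_eff + li * 0.5
                          + gi * effect})
    return pd.DataFrame(rows)


def classical_mixed_anova_f(df):
    """Independent oracle: classical balanced-design partitioned SS."""
    grand = df.dv.mean()
    g_means = df.groupby("genotype").dv.mean()
    k_means = df.groupby("ka_nm").dv.mean()
    s_means = df.groupby("slice_id").dv.mean()
    gk_means = df.groupby(["genotype", "ka_nm"]).dv.mean()
    subj_geno = df.groupby("slice_id").genotype.first()
    n_g, n_k = g_means.size, k_means.size
    n_s_per_g = s_means.size // n_g
    ss_between = n_k * n_s_per_g * ((g_means - grand) ** 2).sum()
    ss_subj = n_k * ((s_means - g_means[subj_geno].to_numpy()) ** 2).sum()
    ss_within = n_g * n_s_per_g * ((k_means - grand) ** 2).sum()
    ss_inter = n_s_per_g * sum(
        (gk_means[g, k] - g_means[g] - k_means[k] + grand) ** 2
        for g in g_means.index for k in k_means.index)
    ss_total = ((df.dv - grand) ** 2).sum()
    ss_res = ss_total - ss_between - ss_subj - ss_within - ss_inter
    df_sub = n_g * (n_s_per_g - 1)
    df_res = df_sub * (n_k - 1)
    return {
        "between": (ss_between / (n_g - 1)) / (ss_subj / df_sub),
        "within": (ss_within / (n_k - 1)) / (ss_res / df_res),
        "interaction": (ss_inter / ((n_g - 1) * (n_k - 1))) / (ss_res / df_res),
    }


class TestMixedAnova:
    def test_matches_classical_partition_on_balanced_data(self):
        df = balanced_table(seed=3, effect=1.0)
        res = mixed_anova(df, dv="dv")
        oracle = classical_mixed_anova_f(df)
        for effect in ("between", "within", "interaction"):
            assert res.table.loc[effect, "F"] == pytest.approx(
                oracle[effect], abs=1e-9)

    def test_matches_pingouin_on_balanced_data(self):
        pingouin = pytest.importorskip("pingouin")
        df = balanced_table(seed=5, effect=0.8)
        res = mixed_anova(df, dv="dv")
        ref = pingouin.mixed_anova(data=df, dv="dv", within="ka_nm",
                                   between="genotype", subject="slice_id")
        ref = ref.set_index("Source")
        assert res.table.loc["between", "F"] == pytest.approx(
            ref.loc["genotype", "F"], abs=1e-6)
        assert res.table.loc["within", "F"] == pytest.approx(
            ref.loc["ka_nm", "F"], abs=1e-6)
        assert res.table.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6)

    def test_constant_dv_degenerate(self):
        df = balanced_table(seed=0)
        df["dv"] = 1.0
        res = mixed_anova(df, dv="dv")
        assert res.pvalue("between") == 1.0
        assert res.table.loc["between", "F"] == 0.0

    def test_rank_transform_invariant_under_monotone_map(self):
        df = balanced_table(seed=7, effect=1.0)
        df["dv"] = df["dv"] - df["dv"].min() + 0.1
        res1 = mixed_anova(df, dv="dv", transform="rank")
        df2 = df.assign(dv=np.exp(df["dv"]))
        res2 = mixed_anova(df2, dv="dv", transform="rank")
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_log10_requires_positive(self):
        df = balanced_table(seed=0)
        with pytest.raises(ValueError, match="positive"):
            mixed_anova(df, dv="dv", transform="log10")

    def test_subject_in_two_groups_rejected(self):
        df = balanced_table(seed=0)
        df.loc[df.index[:3], "slice_id"] = df["slice_id"].iloc[-1]
        with pytest.raises(ValueError, match="more than one"):
            mixed_anova(df, dv="dv")

    def test_handles_missing_cells(self):
        df = balanced_table(seed=9, effect=1.5, n_subj=6)
        df = df.drop(df.index[[2, 10, 17]])  # gate removed some levels
        res = mixed_anova(df, dv="dv")
        assert 0.0 <= res.pvalue("between") <= 1.0
        assert res.table.loc["within", "df2"] < 2 * 6 * 2  # dfs shrink


class TestTukeyHsd:
    def test_identical_groups_p_near_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = tukey_hsd({"a": g, "b": g})
        assert res["p_adj"].iloc[0] > 0.99

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        res = tukey_hsd({"a": rng.normal(0, 0.1, 8),
                         "b": rng.normal(10, 0.1, 8)})
        assert res["p_adj"].iloc[0] < 1e-3

    def test_symmetric_under_relabelling(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(1, 1, 6),
                  "c": rng.normal(2, 1, 6)}
        res1 = tukey_hsd(groups)
        res2 = tukey_hsd({k: groups[k] for k in ("c", "b", "a")})
        p1 = {frozenset((r.group_a, r.group_b)): r.p_adj for r in res1.itertuples()}
        p2 = {frozenset((r.group_a, r.group_b)): r.p_adj for r in res2.itertuples()}
        assert p1 == pytest.approx(p2)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestTwoGroupTest:
    def test_identical_groups_p_one(self):
        stat, p, name = two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0
        assert name == "ttest"

    def test_mannwhitney_enumeration_example(self):
        stat, p, name = two_group_test([1, 2, 3], [1, 2, 3],
                                       method="mannwhitney")
        assert stat == 4.5
        assert p == pytest.approx(1.0)

    def test_skewed_data_routes_nonparametric(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(size=40))
        b = np.exp(rng.normal(size=40))
        _, _, name = two_group_test(a, b)
        assert name == "mannwhitney"

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 10))
            _, p, _ = two_group_test(a, b, method="ttest")
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0])
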