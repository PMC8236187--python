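"""Cell-stage contrasts: t-tests, Tukey HSD and the mixed-model pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import studentized_range

import devclock as dc
from devclock.datamodel import ValidationError


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, computed from scratch."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def tukey_oracle(groups):
    """Tukey-Kramer adjusted p-values from the studentized-range CDF,
    assembled from first principles (group means, pooled MSE)."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    dfe = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / dfe
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            se = np.sqrt(mse / 2 * (1 / len(gi) + 1 / len(gj)))
            q = abs(gj.mean() - gi.mean()) / se
            out[(i, j)] = studentized_range.sf(q, k, dfe)
    return out


class TestTwoSampleT:
    def test_identical_groups(self):
        g = np.array([1.0, 2, 3])
        res = dc.two_sample_t(g, g.copy())
        assert res.delta_mean == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_matches_hand_computation(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        res = dc.two_sample_t(a, b, equal_var=True)
        t_o, p_o = pooled_t_oracle(a, b)
        assert res.statistic == pytest.approx(t_o, abs=1e-12)
        assert res.p_value == pytest.approx(p_o, abs=1e-12)
        assert res.delta_mean == 3.0

    def test_welch_is_default(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=8)
        b = rng.normal(1, 5, size=12)
        res = dc.two_sample_t(a, b)
        ref = stats.ttest_ind(b, a, equal_var=False)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_scale_invariance_of_p(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 7])
        p1 = dc.two_sample_t(a, b).p_value
        p2 = dc.two_sample_t(10 * a, 10 * b).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_variance_equal_means_flagged(self):
        res = dc.two_sample_t(np.array([5.0, 5]), np.array([5.0, 5]))
        assert res.p_value == 1.0
        assert "degenerate" in res.flag

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            dc.two_sample_t(np.array([1.0]), np.array([2.0, 3.0]))


class TestAnovaTukey:
    def test_identical_groups_give_f_zero(self):
        g = np.array([3.0, 3, 3])
        values = np.concatenate([g, g, g])
        stage = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        F, p, contrasts = dc.anova_tukey(values, stage)
        assert F == 0.0 and p == 1.0
        assert all(c.p_value > 0.99 for c in contrasts)

    def test_matches_studentized_range_oracle_balanced(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(mu, 1.0, size=5) for mu in (0.0, 1.0, 3.0)]
        values = np.concatenate(groups)
        stage = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        _, _, contrasts = dc.anova_tukey(values, stage)
        oracle = tukey_oracle(groups)
        got = {tuple(sorted(c.contrast.split("-"))): c.p_value for c in contrasts}
        for (i, j), p_o in oracle.items():
            key = tuple(sorted(("abc"[i], "abc"[j])))
            assert got[key] == pytest.approx(p_o, abs=1e-4)

    def test_matches_oracle_unbalanced(self):
        rng = np.random.default_rng(12)
        groups = [
            rng.normal(0.0, 1.0, size=4),
            rng.normal(1.5, 1.0, size=7),
            rng.normal(2.0, 1.0, size=5),
        ]
        values = np.concatenate(groups)
        stage = np.array(["a"] * 4 + ["b"] * 7 + ["c"] * 5)
        _, _, contrasts = dc.anova_tukey(values, stage)
        oracle = tukey_oracle(groups)
        got = {tuple(sorted(c.contrast.split("-"))): c.p_value for c in contrasts}
        for (i, j), p_o in oracle.items():
            key = tuple(sorted(("abc"[i], "abc"[j])))
            assert got[key] == pytest.approx(p_o, abs=1e-4)

    def test_tukey_adjusted_p_not_below_unadjusted_t(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            groups = [rng.normal(rng.uniform(0, 2), 1.0, size=6) for _ in range(3)]
            values = np.concatenate(groups)
            stage = np.repeat(["a", "b", "c"], 6)
            _, _, contrasts = dc.anova_tukey(values, stage)
            by_pair = {tuple(sorted(c.contrast.split("-"))): c for c in contrasts}
            for (i, j) in [(0, 1), (0, 2), (1, 2)]:
                # unadjusted pairwise test using the pooled 3-group MSE is the
                # natural comparator; the plain 2-group pooled t is close enough
                _, p_t = pooled_t_oracle(groups[i], groups[j])
                c = by_pair[tuple(sorted(("abc"[i], "abc"[j])))]
                assert c.p_value >= p_t - 0.02

    def test_two_stages_rejected(self):
        with pytest.raises(ValidationError, match="3 stages"):
            dc.anova_tukey(np.arange(6.0), np.repeat(["a", "b"], 3))

    def test_stage_with_single_observation_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            dc.anova_tukey(
                np.arange(5.0), np.array(["a", "a", "b", "b", "c"])
            )


class TestPerDatasetContrasts:
    def test_two_and_three_stage_datasets_dispatch(self):
        table, _ = dc.simulate_cellstage_datasets(dc.CellStageSimSpec(seed=3))
        res = dc.per_dataset_contrasts(table)
        methods = res.groupby("dataset_id")["method"].unique()
        assert list(methods["ds1"]) == ["tukey_hsd"]  # three stages
        assert list(methods["ds3"]) == ["t_test"]  # two stages


class TestMixedModel:
    def test_zero_variance_reduces_to_ols(self):
        # no dataset effect, no noise: REML fixed effects == OLS exactly
        spec = dc.CellStageSimSpec(
            dataset_intercept_sd=0.0, residual_sd=0.0, seed=1
        )
        table, truth = dc.simulate_cellstage_datasets(spec)
        fit = dc.stage_meta_analysis(table)
        means = truth["stage_means_dpc"]
        assert fit.fixed_effects["intercept"] == pytest.approx(means["iPSC"], abs=1e-6)
        assert fit.fixed_effects["NPC-iPSC"] == pytest.approx(
            means["NPC"] - means["iPSC"], abs=1e-6
        )
        assert fit.fixed_effects["neuron-iPSC"] == pytest.approx(
            means["neuron"] - means["iPSC"], abs=1e-6
        )

    def test_ols_equivalence_when_noise_but_no_dataset_effect(self):
        import statsmodels.api as sm

        spec = dc.CellStageSimSpec(dataset_intercept_sd=0.0, residual_sd=7.0, seed=2)
        table, _ = dc.simulate_cellstage_datasets(spec)
        fit = dc.stage_meta_analysis(table)
        X = np.column_stack(
            [
                np.ones(len(table)),
                (table["group"] == "NPC").to_numpy(float),
                (table["group"] == "neuron").to_numpy(float),
            ]
        )
        ols = sm.OLS(table["predicted_age_dpc"].to_numpy(), X).fit()
        # estimated random-intercept variance ~ 0 -> fixed effects near OLS
        assert fit.fixed_effects["neuron-iPSC"] == pytest.approx(
            float(ols.params[2]), abs=0.35
        )

    def test_single_dataset_falls_back_to_ols(self):
        spec = dc.CellStageSimSpec(
            n_datasets=1,
            stage_availability={"only": {"iPSC": 6, "neuron": 8}},
            seed=4,
        )
        table, _ = dc.simulate_cellstage_datasets(spec)
        with pytest.warns(UserWarning, match="single dataset"):
            fit = dc.stage_meta_analysis(table)
        assert fit.method == "ols_fallback"
        assert fit.n_datasets == 1

    def test_invariant_to_dataset_relabeling(self):
        table, _ = dc.simulate_cellstage_datasets(dc.CellStageSimSpec(seed=5))
        fit1 = dc.stage_meta_analysis(table)
        relabeled = table.copy()
        relabeled["dataset_id"] = relabeled["dataset_id"].map(
            lambda d: f"study_{d[::-1]}"
        )
        fit2 = dc.stage_meta_analysis(relabeled)
        assert fit1.fixed_effects["neuron-iPSC"] == pytest.approx(
            fit2.fixed_effects["neuron-iPSC"], abs=1e-8
        )
        assert fit1.random_intercept_var == pytest.approx(
            fit2.random_intercept_var, abs=1e-8
        )

    def test_permuted_stage_labels_center_effect_at_zero(self):
        rng = np.random.default_rng(6)
        effects = []
        for rep in range(30):
            table, _ = dc.simulate_cellstage_datasets(dc.CellStageSimSpec(seed=rep))
            permuted = table.copy()
            permuted["group"] = (
                permuted.groupby("dataset_id")["group"]
                .transform(lambda s: rng.permutation(s.to_numpy()))
            )
            fit = dc.stage_meta_analysis(permuted)
            effects.append(fit.fixed_effects["neuron-iPSC"])
        mean_effect = np.mean(effects)
        se = np.std(effects, ddof=1) / np.sqrt(len(effects))
        assert abs(mean_effect) < 3 * se + 0.5

    def test_missing_reference_stage_rejected(self):
        table = pd.DataFrame(
            {
                "predicted_age_dpc": np.arange(8.0),
                "group": ["NPC"] * 4 + ["neuron"] * 4,
                "dataset_id": ["a"] * 4 + ["b"] * 4,
            }
        )
        with pytest.raises(ValidationError, match="reference"):
            dc.stage_meta_analysis(table)
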