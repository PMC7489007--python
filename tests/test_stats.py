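"""Decision-tree statistics: gates, test mapping, permutation, Holm-Sidak."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from swdkit.stats import (
    GroupComparison,
    StatsConfig,
    assess_normality,
    assess_variance,
    holm_sidak,
    permutation_test,
    run_comparison,
    select_test,
)


class TestHolmSidak:
    def test_single_p_is_identity(self):
        assert holm_sidak([0.05]) == pytest.approx([0.05])

    def test_all_zero(self):
        assert holm_sidak([0.0, 0.0, 0.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_hand_evaluated_example(self):
        # sorted {0.01, 0.03, 0.04}: 1-(0.99)^3, 1-(0.97)^2, then the last
        # raw adjustment 0.04 is lifted to the running maximum 0.0591
        adj = holm_sidak([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.029701, 0.0591, 0.0591])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 8)))
            _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
            np.testing.assert_allclose(holm_sidak(p), adj_sm, rtol=1e-10)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 10)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


class TestPermutationTest:
    def test_exact_small_case(self):
        assert permutation_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_one(self):
        assert permutation_test([5.0, 7.0, 9.0], [9.0, 5.0, 7.0]) == pytest.approx(1.0)

    def test_label_exchange_invariance(self):
        a, b = [1.0, 3.0, 2.0, 8.0], [4.0, 6.0, 9.0, 2.0]
        assert permutation_test(a, b) == permutation_test(b, a)

    def test_monte_carlo_tracks_exact(self):
        rng = np.random.default_rng(17)
        n_perm = 4000
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.8, 1, 6)
            exact = permutation_test(a, b)  # C(12,6)=924 -> enumerated
            mc = permutation_test(
                a, b, StatsConfig(exact_enumeration_limit=10, n_permutations=n_perm, seed=3)
            )
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc - exact) <= 3 * se + 1 / n_perm

    def test_exact_path_agrees_with_scipy(self):
        """Independent oracle: scipy's exhaustive permutation test.

        scipy's two-sided p is 2x the smaller one-sided tail, which can
        differ from the |mean difference| counting convention by boundary
        arrangements; agreement is asserted to within 2 arrangements.
        """
        from math import comb

        from scipy import stats as sst

        rng = np.random.default_rng(4)
        for _ in range(10):
            na, nb = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            a, b = rng.normal(0, 1, na), rng.normal(1, 1, nb)
            mine = permutation_test(a, b)
            ref = sst.permutation_test(
                (a, b),
                lambda x, y: np.mean(x) - np.mean(y),
                permutation_type="independent",
                alternative="two-sided",
                n_resamples=np.inf,
            ).pvalue
            assert abs(mine - ref) <= 2.0 / comb(na + nb, na) + 1e-12

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        cfg = StatsConfig(seed=11, n_permutations=500)
        assert permutation_test(a, b, cfg) == permutation_test(a, b, cfg)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])


class TestNormalityGate:
    def test_gaussian_groups_pass(self):
        rng = np.random.default_rng(8)
        samples = {"a": rng.normal(0, 1, 100), "b": rng.normal(5, 2, 100)}
        normal, transformed, _, _ = assess_normality(samples)
        assert all(normal.values())
        assert not transformed

    def test_lognormal_rescued_by_log_transform(self):
        rng = np.random.default_rng(9)
        samples = {"a": rng.lognormal(0, 1, 200), "b": rng.lognormal(0.5, 1, 200)}
        normal, transformed, work, _ = assess_normality(samples)
        assert all(normal.values())
        assert transformed
        np.testing.assert_allclose(work["a"], np.log(samples["a"]))

    def test_zero_values_block_log_transform(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.lognormal(0, 1.5, 199), [0.0]])
        normal, transformed, _, trace = assess_normality({"a": x, "b": rng.lognormal(0, 1.5, 200)})
        assert not all(normal.values())
        assert not transformed
        assert any("non-positive" in step["outcome"] for step in trace)

    def test_small_group_treated_as_non_normal_with_warning(self):
        rng = np.random.default_rng(11)
        with pytest.warns(UserWarning, match="too small"):
            normal, _, _, _ = assess_normality({"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 50)})
        assert normal["a"] is False


class TestVarianceGate:
    def test_duplicated_group_f_statistic_is_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 40)
        equal, step = assess_variance({"a": x, "b": x.copy()}, normal=True)
        assert equal
        assert step["statistic"] == pytest.approx(1.0)
        assert "F test" in step["gate"]

    def test_three_normal_groups_use_bartlett(self):
        rng = np.random.default_rng(13)
        _, step = assess_variance(
            {g: rng.normal(0, 1, 30) for g in "abc"}, normal=True
        )
        assert "Bartlett" in step["gate"]

    def test_non_normal_uses_brown_forsythe(self):
        rng = np.random.default_rng(14)
        _, step = assess_variance(
            {g: rng.lognormal(0, 1, 30) for g in "ab"}, normal=False
        )
        assert "Brown-Forsythe" in step["gate"]

    def test_threefold_sigma_ratio_detected(self):
        rng = np.random.default_rng(15)
        equal, _ = assess_variance(
            {"a": rng.normal(0, 1, 100), "b": rng.normal(0, 3, 100)}, normal=True
        )
        assert not equal

    def test_zero_variance_group_unequal_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            equal, _ = assess_variance({"a": np.ones(10), "b": np.arange(10.0)}, normal=True)
        assert not equal


class TestSelectTest:
    def _normal(self, rng, n=60, loc=0.0, scale=1.0):
        return rng.normal(loc, scale, n)

    def test_two_normal_equal_variance_maps_to_t(self):
        rng = np.random.default_rng(20)
        plan, _ = select_test({"a": self._normal(rng), "b": self._normal(rng)})
        assert plan.chosen_test == "t"

    def test_two_normal_unequal_variance_maps_to_welch(self):
        rng = np.random.default_rng(21)
        plan, _ = select_test(
            {"a": self._normal(rng, scale=1.0), "b": self._normal(rng, scale=5.0)}
        )
        assert plan.chosen_test == "welch_t"

    def test_three_normal_equal_maps_to_anova_holm_sidak(self):
        rng = np.random.default_rng(20)
        plan, _ = select_test({g: self._normal(rng) for g in "abc"})
        assert plan.chosen_test == "anova_holm_sidak"

    def test_three_normal_unequal_maps_to_welch_holm_sidak(self):
        rng = np.random.default_rng(23)
        plan, _ = select_test(
            {"a": self._normal(rng), "b": self._normal(rng), "c": self._normal(rng, scale=6.0)}
        )
        assert plan.chosen_test == "welch_t_holm_sidak"

    def test_non_normal_equal_maps_to_kruskal_dunn(self):
        rng = np.random.default_rng(24)
        samples = {g: rng.standard_t(2, 80) for g in "abc"}  # heavy tails, equal spread
        plan, _ = select_test(samples)
        assert not plan.all_normal
        if plan.variance_equal:
            assert plan.chosen_test == "kruskal_wallis_dunn"

    def test_non_normal_unequal_maps_to_permutation(self):
        rng = np.random.default_rng(26)
        samples = {
            "a": rng.standard_t(2, 120),
            "b": rng.standard_t(2, 120) * 8.0,
            "c": np.abs(rng.standard_t(2, 120)) * 4.0,  # skewed: blocks log rescue? values>0
        }
        samples["c"] = samples["c"] - 2.0  # ensure non-positive so log not attempted
        plan, _ = select_test(samples)
        assert plan.chosen_test == "permutation_holm_sidak"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            select_test({"a": np.arange(10.0)})

    def test_trace_replays_choice(self):
        rng = np.random.default_rng(27)
        plan, _ = select_test({g: self._normal(rng) for g in "abc"})
        assert plan.decision_trace[-1]["outcome"] == plan.chosen_test
        gates = [s["gate"] for s in plan.decision_trace]
        assert any(g.startswith("normality") for g in gates)
        assert any(g.startswith("variance") for g in gates)


class TestRunComparison:
    def test_three_shifted_groups_detected(self):
        rng = np.random.default_rng(30)
        samples = {
            "wt": rng.normal(0, 1, 15),
            "tg": rng.normal(1.6, 1, 15),
            "ki": rng.normal(0, 1, 15),
        }
        res = run_comparison(samples)
        assert res.significant
        row = res.comparisons.set_index(["group_a", "group_b"])
        assert row.loc[("wt", "tg"), "p_adjusted"] < 0.05

    def test_constant_equal_groups_not_significant(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_comparison({"a": [2.0] * 10, "b": [2.0] * 10, "c": [2.0] * 10})
        assert not res.significant

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(31)
        res = run_comparison({g: rng.normal(0, 1, 20) for g in "abcd"})
        assert (res.comparisons["p_adjusted"] >= res.comparisons["p_raw"] - 1e-15).all()

    def test_from_dataframe_matches_dict(self):
        rng = np.random.default_rng(32)
        samples = {"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12)}
        df = pd.DataFrame(
            [{"group": g, "value": v} for g, vs in samples.items() for v in vs]
        )
        r1 = GroupComparison(samples).fit()
        r2 = GroupComparison.from_dataframe(df).fit()
        pd.testing.assert_frame_equal(r1.comparisons, r2.comparisons)

    def test_summary_mentions_choice_and_pairs(self):
        rng = np.random.default_rng(33)
        res = run_comparison({g: rng.normal(0, 1, 30) for g in ("wt", "j20")})
        text = res.summary()
        assert "chosen test" in text
        assert "wt vs j20" in text
        assert "decision trace" in text

    def test_permutation_branch_runs_end_to_end(self):
        rng = np.random.default_rng(34)
        samples = {
            "a": rng.standard_t(2, 40) - 1.0,
            "b": rng.standard_t(2, 40) * 6.0,
            "c": rng.standard_t(2, 40),
        }
        cfg = StatsConfig(n_permutations=500, seed=5)
        res = GroupComparison(samples, cfg).fit()
        if res.plan.chosen_test == "permutation_holm_sidak":
            assert len(res.comparisons) == 3
            assert res.comparisons["p_raw"].between(0, 1).all()
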