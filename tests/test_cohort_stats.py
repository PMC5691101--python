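"""Group statistics: ANOVA + Tukey HSD, Pearson correlation, growth tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from epr_oximetry import (
    CohortDesign,
    ValidationError,
    anova_tukey,
    growth_comparison,
    growth_significance_sweep,
    pearson_correlation,
    simulate_cohort_table,
)


class TestAnovaTukey:
    def test_hand_computed_three_group_fixture(self):
        """{1,2,3}, {2,3,4}, {5,6,7}: SSB=26, SSW=6 -> F = 13.0 on (2, 6) df."""
        values = [1, 2, 3, 2, 3, 4, 5, 6, 7]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        gs = anova_tukey(values, groups)
        assert gs.f_statistic == pytest.approx(13.0, rel=1e-12)
        assert (gs.df_between, gs.df_within) == (2, 6)
        assert gs.anova_p == pytest.approx(sp_stats.f.sf(13.0, 2, 6), rel=1e-12)

    def test_all_equal_gives_f_zero_p_one(self):
        gs = anova_tukey([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert gs.f_statistic == 0.0
        assert gs.anova_p == 1.0
        assert all(p == 1.0 for p in gs.tukey_p.values())

    def test_two_groups_match_pooled_t_via_q_identity(self, rng):
        """With two groups the studentized range reduces to q = sqrt(2)|t|,
        so Tukey's adjusted p equals the pooled-variance t-test p."""
        for _ in range(5):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.8, 1, 11)
            gs = anova_tukey(
                np.concatenate([a, b]), ["a"] * 8 + ["b"] * 11
            )
            t_p = sp_stats.ttest_ind(a, b, equal_var=True).pvalue
            assert gs.tukey_p[("a", "b")] == pytest.approx(t_p, rel=1e-6)

    def test_matches_statsmodels_on_three_groups(self, rng):
        """Independent cross-check against statsmodels pairwise_tukeyhsd."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(
            [rng.normal(0, 1, 7), rng.normal(1, 1, 9), rng.normal(2, 1, 8)]
        )
        groups = np.array(["a"] * 7 + ["b"] * 9 + ["c"] * 8)
        gs = anova_tukey(values, groups)
        sm_res = pairwise_tukeyhsd(values, groups)
        for (pair, p_sm) in zip(
            [("a", "b"), ("a", "c"), ("b", "c")], sm_res.pvalues
        ):
            assert gs.tukey_p[pair] == pytest.approx(p_sm, abs=1e-6)

    def test_tukey_p_not_below_unadjusted_pairwise_p(self, rng):
        """Tukey adjusted p >= the unadjusted (LSD-style) pairwise p built
        from the same pooled within-group variance."""
        values = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(0.5, 1, 6), rng.normal(1.2, 1, 6)]
        )
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        gs = anova_tukey(values, groups)
        msw = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in "abc"
        ) / gs.df_within
        for gi, gj in gs.tukey_p:
            a, b = values[groups == gi], values[groups == gj]
            t = abs(a.mean() - b.mean()) / np.sqrt(msw * (1 / a.size + 1 / b.size))
            raw_p = 2 * sp_stats.t.sf(t, gs.df_within)
            assert gs.tukey_p[(gi, gj)] >= raw_p - 1e-12

    def test_tukey_monotone_in_effect_size(self, rng):
        """Growing one group's mean shift (same noise draws) never increases
        that pair's adjusted p."""
        base_a = rng.normal(0, 1, 10)
        base_b = rng.normal(0, 1, 10)
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            gs = anova_tukey(
                np.concatenate([base_a, base_b + shift]), ["a"] * 10 + ["b"] * 10
            )
            ps.append(gs.tukey_p[("a", "b")])
        assert np.all(np.diff(ps) <= 1e-12)

    def test_small_group_error_names_group(self):
        with pytest.raises(ValidationError, match="'b'"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_summary_mentions_f_and_groups(self):
        gs = anova_tukey([1, 2, 3, 2, 3, 4, 5, 6, 7],
                         ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        text = gs.summary()
        assert "F(2, 6) = 13" in text
        assert "a vs c" in text


class TestPearson:
    def test_perfect_anticorrelation(self):
        res = pearson_correlation([1, 2, 3], [6, 4, 2])
        assert res.r == pytest.approx(-1.0)
        assert res.p == 0.0
        assert res.n == 3

    def test_zero_correlation_gives_p_one(self):
        res = pearson_correlation([1.0, 2.0, 3.0, 4.0], [-1.0, 1.0, 1.0, -1.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_exact_p(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_correlation(x, y)
        ref = sp_stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Quick null calibration: 400 independent reps at n = 20 give
        p-values compatible with Uniform(0,1) (KS)."""
        rng = np.random.default_rng(17)
        ps = [
            pearson_correlation(rng.normal(size=20), rng.normal(size=20)).p
            for _ in range(400)
        ]
        assert sp_stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])


class TestGrowth:
    @staticmethod
    def table_from(control, treated, day=21):
        rows = []
        for i, v in enumerate(control):
            rows.append((f"C{i}", f"C{i}-T1", "control", 0.0, 10.0, day, v))
        for i, v in enumerate(treated):
            rows.append((f"T{i}", f"T{i}-T1", "treated", 0.0, 10.0, day, v))
        return pd.DataFrame(rows, columns=[
            "animal_id", "tumour_id", "group", "probe_position_cm",
            "pO2_true_mmHg", "day", "volume_mm3",
        ])

    def test_identical_groups_give_p_one(self):
        vols = [100.0, 120.0, 140.0, 160.0]
        gc = growth_comparison(self.table_from(vols, vols), 21)
        assert gc.p == pytest.approx(1.0)
        assert not gc.significant

    def test_label_swap_leaves_p_unchanged(self, rng):
        a = list(rng.normal(200, 30, 8))
        b = list(rng.normal(150, 30, 8))
        p1 = growth_comparison(self.table_from(a, b), 21).p
        p2 = growth_comparison(self.table_from(b, a), 21).p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_missing_day_error_lists_available(self):
        with pytest.raises(ValidationError, match=r"available days"):
            growth_comparison(self.table_from([1.0, 2.0], [3.0, 4.0]), 5)

    def test_final_day_power_in_default_design(self):
        """Treatment halves the growth rate; at n = 12 tumours/group the
        final-day Welch test is significant in >= 80% of 200 cohorts."""
        hits = 0
        for rep in range(200):
            d = CohortDesign(rng_seed=50_000 + rep)
            table = simulate_cohort_table(d)
            gc = growth_comparison(table, max(d.measurement_days))
            hits += gc.significant
        assert hits / 200 >= 0.80

    def test_sweep_covers_every_day(self):
        d = CohortDesign(n_animals_per_group=3, rng_seed=1)
        table = simulate_cohort_table(d)
        sweep = growth_significance_sweep(table)
        assert list(sweep["day"]) == sorted(d.measurement_days)
        assert {"p", "significant"} <= set(sweep.columns)
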