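import itertools

import numpy as np
import pytest

from exclusim import (
    ScenarioConfig,
    add_ue_columns,
    build_baseline_table,
    chi_squared_test,
    pooled_t_test,
    sample_cohort,
    wilcoxon_rank_sum,
)
from exclusim.tables import render_baseline_table


class TestChiSquared:
    def test_sex_table(self):
        # 60/13 females/males in the low-UE half vs 40/32 in the high half
        stat, df, p = chi_squared_test([[60, 13], [40, 32]])
        assert stat == pytest.approx(12.016, abs=5e-3)
        assert df == 1
        assert p == pytest.approx(0.0005, abs=5e-5)

    def test_hispanic_table(self):
        _, _, p = chi_squared_test([[13, 60], [8, 64]])
        assert p == pytest.approx(0.2519, abs=5e-5)

    def test_race_table(self):
        stat, df, p = chi_squared_test([[59, 55], [5, 10], [3, 2], [6, 5]])
        assert df == 3
        assert p == pytest.approx(0.5537, abs=5e-5)

    def test_identical_proportions_give_zero(self):
        stat, _, p = chi_squared_test([[20, 40], [10, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = np.array([[59, 55], [5, 10], [3, 2], [6, 5]])
        s0 = chi_squared_test(t)[0]
        for perm in itertools.permutations(range(4)):
            assert chi_squared_test(t[list(perm)])[0] == pytest.approx(s0)
        assert chi_squared_test(t[:, ::-1])[0] == pytest.approx(s0)

    def test_zero_marginal_named(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chi_squared_test([[0, 0], [5, 10]])


class TestPooledT:
    def test_weight_row_from_printed_summaries(self):
        """Frozen hand oracle: pooled SE 2.9687, t = -2.8632, p = 0.00483.

        The published table prints p = 0.0045 for this row; rounding of the
        printed means/SDs to 3 significant figures propagates ~4e-4 in p,
        which is the agreement asserted against the printed value.
        """
        t, df, p = pooled_t_test(87.1, 16.8, 73, 95.6, 18.9, 72)
        assert df == 143
        assert t == pytest.approx(-2.8632, abs=5e-4)
        assert p == pytest.approx(0.004825, abs=5e-6)  # exact oracle
        assert p == pytest.approx(0.0045, abs=5e-4)  # printed, within rounding

    def test_baseline_tee_row_from_printed_summaries(self):
        # 2841 (672), n=72 vs 3180 (729), n=70 (three TEE values missing)
        _, _, p = pooled_t_test(2841, 672, 72, 3180, 729, 70)
        assert p == pytest.approx(0.0045, abs=1e-4)

    def test_identical_summaries(self):
        t, _, p = pooled_t_test(10, 2, 30, 10, 2, 30)
        assert t == 0.0 and p == 1.0

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 35)
        t1, df1, p1 = pooled_t_test(sample1=a, sample2=b)
        t2, df2, p2 = pooled_t_test(a.mean(), a.std(ddof=1), 40,
                                    b.mean(), b.std(ddof=1), 35)
        assert t1 == pytest.approx(t2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_zero_variance_unequal_means(self):
        t, _, p = pooled_t_test(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert p == 0.0 and np.isinf(t)


class TestWilcoxon:
    def test_most_extreme_small_case(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 splits, x2 sides
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([3, 3, 3], [3, 3])
        assert p == 1.0

    def test_normal_approximation_tracks_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
            _, p_exact = wilcoxon_rank_sum(a, b)  # n=12 -> enumeration
            _, p_norm = wilcoxon_rank_sum(a, b, exact_max_n=0)
            assert abs(p_exact - p_norm) < 0.02
        for _ in range(25):
            a = rng.integers(0, 8, 6).astype(float)  # heavy integer ties
            b = rng.integers(0, 8, 6).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            _, p_exact = wilcoxon_rank_sum(a, b)
            _, p_norm = wilcoxon_rank_sum(a, b, exact_max_n=0)
            # heavy ties at n=12 stress the approximation; agreement is
            # correspondingly looser than in the continuous case
            assert abs(p_exact - p_norm) < 0.08

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBaselineTable:
    def test_renders_all_variables(self, cohort, config):
        rows = build_baseline_table(cohort)
        assert len(rows) == 12
        rendered = render_baseline_table(rows)
        assert list(rendered.columns) == [
            "Variable", "Total", "Low UE", "High UE", "Test", "P value"]
        assert all(0 <= r.p_value <= 1 for r in rows)

    def test_requires_grouping_column(self, config):
        df = sample_cohort(config, seed=3)
        with pytest.raises(ValueError, match="ue_group"):
            build_baseline_table(df)

    def test_coin_flip_grouping_is_null(self, config):
        """Grouping by a fair coin: ~5% of rows significant at 0.05."""
        rng = np.random.default_rng(11)
        hits = total = 0
        for r in range(120):
            df = sample_cohort(config, seed=70_000 + r)
            df["ue_group"] = np.where(rng.random(len(df)) < 0.5, "low", "high")
            for row in build_baseline_table(df):
                if np.isfinite(row.p_value):
                    total += 1
                    hits += row.p_value < 0.05
        frac = hits / total
        assert 0.02 < frac < 0.09

    def test_confounded_scenario_reproduces_imbalance_directions(self, config):
        """Grouping by UE: the high-UE half is more male, heavier, has
        higher baseline TEE and lost less weight in the run-in."""
        ps = {k: [] for k in ("female", "weight", "tee")}
        gaps = {k: [] for k in ("female", "weight", "tee", "runin")}
        for r in range(30):
            df = add_ue_columns(sample_cohort(config, seed=80_000 + r), config)
            lo, hi = df[df["ue_group"] == "low"], df[df["ue_group"] == "high"]
            gaps["weight"].append(hi["weight"].mean() - lo["weight"].mean())
            gaps["tee"].append(hi["tee_baseline_measured"].mean()
                               - lo["tee_baseline_measured"].mean())
            gaps["female"].append(hi["female"].mean() - lo["female"].mean())
            gaps["runin"].append(hi["runin_loss"].mean() - lo["runin_loss"].mean())
            rows = {x.variable: x for x in build_baseline_table(df)}
            ps["female"].append(rows["Female, N (%)"].p_value)
            ps["weight"].append(rows["Weight (kg), Mean (SD)"].p_value)
            ps["tee"].append(rows["Baseline TEE (kcal/d), Mean (SD)"].p_value)
        # the excluded (high-UE) half is heavier, higher-TEE, more male,
        # and lost less weight during the run-in
        assert np.mean(gaps["weight"]) > 0
        assert np.mean(gaps["tee"]) > 0
        assert np.mean(gaps["female"]) < 0
        assert np.mean(gaps["runin"]) < 0
        for k, vals in ps.items():
            assert np.median(vals) < 0.05, k
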