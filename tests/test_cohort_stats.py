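"""Score conversions, Spearman, and the longitudinal test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldmetrics import (
    CohortConfig,
    correlation_table,
    longitudinal_tests,
    mean_mcharts,
    sample_cohort,
    spearman,
    to_logmar,
)
from foldmetrics.cohort_stats import _wilcoxon


def make_cohort(values_by_tp, extra_cols=None):
    """Tidy 3-timepoint cohort from a dict timepoint -> per-eye values."""
    rows = []
    tps = list(values_by_tp)
    n = len(values_by_tp[tps[0]])
    for tp in tps:
        for e in range(n):
            row = {
                "eye_id": f"e{e}",
                "timepoint": tp,
                "density_pct": float(values_by_tp[tp][e]),
                "mv": 0.5,
                "mh": 0.3,
                "mean_mcharts": 0.4,
            }
            if extra_cols:
                row.update({k: v[tp][e] for k, v in extra_cols.items()})
            rows.append(row)
    return pd.DataFrame(rows)


class TestConversions:
    @pytest.mark.parametrize(
        "acuity,expected",
        [("CF", 2.0), ("HM", 2.30), (1.0, 0.0), (0.1, 1.0), (0.5, math.log10(2))],
    )
    def test_logmar_conversion(self, acuity, expected):
        assert to_logmar(acuity) == pytest.approx(expected)

    def test_logmar_rejects_bad_input(self):
        with pytest.raises(ValueError):
            to_logmar(0.0)
        with pytest.raises(ValueError):
            to_logmar("NLP")

    @pytest.mark.parametrize(
        "mv,mh,expected", [(0.68, 0.56, 0.62), (0, 0, 0), (0.34, 0.26, 0.30)]
    )
    def test_mean_mcharts(self, mv, mh, expected):
        assert mean_mcharts(mv, mh) == pytest.approx(expected)

    def test_mean_mcharts_rejects_negative(self):
        with pytest.raises(ValueError):
            mean_mcharts(-0.1, 0.3)


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        x = np.arange(8.0)
        r, p = spearman(x, x**3 + 2)
        assert r == 1.0

    def test_small_example_exact_value(self):
        # d = (1, 1, 1, 1, 0): r = 1 - 6*4 / (5*24) = 0.8... recompute:
        # ranks x = 1..5, ranks y = (2,1,4,3,5), sum d^2 = 1+1+1+1+0 = 4
        # r = 1 - 24/120 = 0.8; the classic 0.7 example uses sum d^2 = 6
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(12, 40))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, _ = spearman(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_is_undefined_not_zero(self):
        r, p = spearman([1.0, 1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4, 5])
        assert math.isnan(r) and math.isnan(p)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        r_obs, p = spearman(x, y)
        # brute-force two-sided permutation p over all 7! pairings
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        count = total = 0
        for perm in itertools.permutations(rx):
            rr = np.corrcoef(perm, ry)[0, 1]
            count += abs(rr) >= abs(r_obs) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)


class TestAgainstExactEnumeration:
    def test_wilcoxon_exact_p_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.3, 1, 8)
        b = rng.normal(0.0, 1, 8)
        stat, p = _wilcoxon(a, b)
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mu = ranks.sum() / 2
        count = total = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = ranks[np.array(signs, bool)].sum()
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_mannwhitney_exact_p_matches_combination_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1, 5)
        b = rng.normal(0.0, 1, 5)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:5].sum() - 5 * 6 / 2
        mu = 5 * 5 / 2
        count = total = 0
        for comb in itertools.combinations(range(10), 5):
            u = ranks[list(comb)].sum() - 5 * 6 / 2
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert res.pvalue == pytest.approx(count / total, abs=1e-12)

    def test_friedman_statistic_matches_rank_formula(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(7, 3))  # 7 eyes, 3 timepoints, no ties
        res = stats.friedmanchisquare(*data.T)
        ranks = np.apply_along_axis(stats.rankdata, 1, data)
        rj = ranks.sum(axis=0)
        n, k = data.shape
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)


class TestLongitudinalBattery:
    def test_identical_values_give_zero_statistic_and_no_posthoc(self):
        vals = {"month1": [1, 2, 3, 4], "month3": [1, 2, 3, 4],
                "month6": [1, 2, 3, 4]}
        report = longitudinal_tests(make_cohort(vals))
        density = report.friedman.set_index("outcome").loc["density"]
        assert density.statistic == 0.0 and density.p == 1.0
        if len(report.pairwise):
            assert "density" not in set(report.pairwise.outcome)

    def test_strict_decline_gives_friedman_ten(self):
        # 5 eyes, identical orderings m1 > m3 > m6: chi2_F = 10 exactly
        vals = {
            "month1": [10, 11, 12, 13, 14],
            "month3": [7, 8, 9, 9.5, 9.8],
            "month6": [1, 2, 3, 4, 5],
        }
        report = longitudinal_tests(make_cohort(vals))
        assert report.friedman.set_index("outcome").loc[
            "density"
        ].statistic == pytest.approx(10.0)

    def test_synthetic_cohort_density_declines_significantly(self):
        df = sample_cohort(CohortConfig(n_eyes=2000), seed=11)
        report = longitudinal_tests(df)
        m1 = df[df.timepoint == "month1"].density_pct.mean()
        m6 = df[df.timepoint == "month6"].density_pct.mean()
        assert m1 > m6
        row = report.pairwise[
            (report.pairwise.outcome == "density")
            & (report.pairwise.comparison == "month1 vs month6")
        ].iloc[0]
        assert row.p_bonferroni < 0.05

    def test_missing_timepoint_names_offending_eye(self):
        df = make_cohort(
            {"month1": [1, 2, 3], "month3": [1, 2, 3], "month6": [1, 2, 3]}
        )
        df = df.drop(df[(df.eye_id == "e1") & (df.timepoint == "month6")].index)
        with pytest.raises(ValueError, match="e1"):
            longitudinal_tests(df)

    def test_bonferroni_caps_at_one(self):
        df = sample_cohort(CohortConfig(n_eyes=12), seed=12)
        report = longitudinal_tests(df)
        if len(report.pairwise):
            assert (report.pairwise.p_bonferroni <= 1.0).all()
            assert (
                report.pairwise.p_bonferroni
                >= report.pairwise.p_raw - 1e-15
            ).all()

    def test_group_comparisons_cover_each_timepoint(self):
        df = sample_cohort(CohortConfig(n_eyes=30), seed=13)
        report = longitudinal_tests(df)
        g = report.group_comparisons
        assert set(g.timepoint) == {"month1", "month3", "month6"}
        assert set(g.comparison) == {"mv vs mh", "vertical vs horizontal"}
        assert (g.test == "mannwhitneyu").all()

    def test_report_is_pure_function_of_table(self):
        df = sample_cohort(CohortConfig(n_eyes=15), seed=14)
        r1 = longitudinal_tests(df)
        r2 = longitudinal_tests(df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(r1.friedman, r2.friedman)
        pd.testing.assert_frame_equal(r1.spearman, r2.spearman)


class TestCorrelationTable:
    def test_upper_triangle_layout(self):
        df = sample_cohort(CohortConfig(n_eyes=20), seed=15)
        table = correlation_table(df)
        # 2 metrics x 6 ordered timepoint pairs
        assert len(table) == 12
        order = {"month1": 0, "month3": 1, "month6": 2}
        assert all(
            order[r.metric_timepoint] <= order[r.mcharts_timepoint]
            for r in table.itertuples()
        )

    def test_constant_metric_reported_as_nan(self):
        vals = {"month1": [5, 5, 5, 5], "month3": [1, 2, 3, 4],
                "month6": [1, 2, 3, 4]}
        extra = {"mv": {tp: [0.1 * i for i in range(4)] for tp in vals}}
        df = make_cohort(vals)
        df["mv"] = np.tile(np.arange(4) * 0.1, 3)
        df["mean_mcharts"] = (df.mv + df.mh) / 2
        table = correlation_table(df, fold_metrics=("density_pct",))
        r_m1 = table[table.metric_timepoint == "month1"].r
        assert r_m1.isna().all()
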