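"""Cohort statistics against brute-force sum-formula oracles."""

import numpy as np
import pandas as pd
import pytest

import dwialps as d
from dwialps.cohort_stats import icc_2_1

# ---------------------------------------------------------------------------
# Independent oracles: explicit textbook sum formulas, no library calls.
# ---------------------------------------------------------------------------

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den


def ols_oracle(x_design, y):
    """Normal equations solved directly."""
    x_design = np.asarray(x_design, float)
    return np.linalg.solve(x_design.T @ x_design, x_design.T @ np.asarray(y, float))


def anova_f_oracle(groups):
    """Between/within sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def _table_from_pairs(ages, a, b):
    return d.CohortTable.from_records(
        pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(ages))],
             "age": ages, "index_obs_A": a, "index_obs_B": b}
        )
    )


# ---------------------------------------------------------------------------


class TestInterobserverCorrelation:
    def test_identical_observers_r_one(self):
        vals = [1.1, 1.3, 1.5, 1.2]
        t = _table_from_pairs([20, 30, 40, 50], vals, vals)
        r, _ = d.interobserver_correlation(t)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        t = _table_from_pairs([20, 30], [1.0, 2.0], [2.0, 1.0])
        r, _ = d.interobserver_correlation(t)
        assert r == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(7)
        a = 1.5 + rng.normal(0, 0.1, 30)
        b = a + rng.normal(0, 0.05, 30)
        ages = rng.integers(10, 90, 30)
        r, (lo, hi) = d.interobserver_correlation(_table_from_pairs(ages, a, b))
        assert r == pytest.approx(pearson_oracle(a, b), abs=1e-12)
        assert lo < r < hi

    def test_missing_observer_lists_subjects(self):
        t = _table_from_pairs([20, 30], [1.0, 1.2], [1.0, np.nan])
        with pytest.raises(ValueError, match="s1"):
            d.interobserver_correlation(t)

    def test_fisher_ci_narrows_with_n(self):
        rng = np.random.default_rng(1)
        a_small = 1.5 + rng.normal(0, 0.1, 20)
        b_small = a_small + rng.normal(0, 0.08, 20)
        big = np.tile(a_small, 10), np.tile(b_small, 10)
        _, (lo_s, hi_s) = d.interobserver_correlation(
            _table_from_pairs(rng.integers(10, 90, 20), a_small, b_small)
        )
        _, (lo_b, hi_b) = d.interobserver_correlation(
            _table_from_pairs(rng.integers(10, 90, 200), *big)
        )
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_icc_penalizes_offset_pearson_does_not(self):
        rng = np.random.default_rng(3)
        a = 1.5 + rng.normal(0, 0.1, 50)
        t = _table_from_pairs(rng.integers(10, 90, 50), a, a + 0.3)
        r, _ = d.interobserver_correlation(t)
        assert r == pytest.approx(1.0)
        assert icc_2_1(t) < 0.9


class TestLinearFit:
    def test_collinear_points(self):
        t = _table_from_pairs([11, 12, 13], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        fit = d.linear_fit(t)
        assert fit.r == pytest.approx(1.0)
        assert fit.coefficients[1] == pytest.approx(1.0, rel=1e-10)

    def test_flat_points_zero_slope(self):
        t = _table_from_pairs([11, 12, 13], [2.0] * 3, [2.0] * 3)
        fit = d.linear_fit(t)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self):
        t = d.generate_cohort(seed=11)
        fit = d.linear_fit(t)
        ages = t.df["age"].to_numpy(float)
        y = t.df["mean_index"].to_numpy(float)
        beta = ols_oracle(np.column_stack([np.ones_like(ages), ages]), y)
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-10)
        assert fit.r == pytest.approx(pearson_oracle(ages, y), abs=1e-10)

    def test_subgroup_filter_is_strict(self):
        ages = [39, 40, 41, 50, 60]
        t = _table_from_pairs(ages, [1.0, 1.1, 1.2, 1.3, 1.4],
                              [1.0, 1.1, 1.2, 1.3, 1.4])
        fit = d.linear_fit(t, min_age=40)
        assert fit.n == 3  # ages 41, 50, 60: "older than 40" excludes 40

    def test_too_few_records_raises(self):
        t = _table_from_pairs([20, 30], [1.0, 1.1], [1.0, 1.1])
        with pytest.raises(ValueError, match=">= 3"):
            d.linear_fit(t)


class TestQuadraticFit:
    def test_exact_parabola_vertex_and_unit_r(self):
        ages = [15, 30, 45, 60, 80]
        y = [100.0 - (a - 45) ** 2 / 100 for a in ages]
        t = _table_from_pairs(ages, y, y)
        fit = d.quadratic_fit(t)
        assert fit.big_r == pytest.approx(1.0, abs=1e-9)
        assert fit.vertex_age == pytest.approx(45.0, abs=1e-8)

    def test_collinear_data_nested_model_limit(self):
        ages = [10, 25, 40, 55, 70, 85]
        y = [1.0 + 0.01 * a for a in ages]
        t = _table_from_pairs(ages, y, y)
        quad = d.quadratic_fit(t)
        lin = d.linear_fit(t)
        assert abs(quad.coefficients[2]) < 1e-10
        assert quad.big_r == pytest.approx(abs(lin.r), abs=1e-9)

    def test_degenerate_design_raises(self):
        t = _table_from_pairs([40] * 5, [1.0, 1.1, 1.2, 1.3, 1.4],
                              [1.0, 1.1, 1.2, 1.3, 1.4])
        with pytest.raises(ValueError, match="degenerate design"):
            d.quadratic_fit(t)

    def test_nesting_r_ge_abs_linear_r_over_random_tables(self):
        """Model nesting: sqrt(R^2) of the quadratic fit can never fall below
        |r| of the linear fit on the same data."""
        for seed in range(20):
            t = d.generate_cohort(seed=seed)
            assert d.quadratic_fit(t).big_r >= abs(d.linear_fit(t).r) - 1e-12

    def test_vertex_recovery_over_seeds(self):
        """Generative peak age 45, subject noise SD 0.1, n=128 cohorts: the
        mean fitted vertex over 100 seeds lands within +/-5 years."""
        vs = [d.quadratic_fit(d.generate_cohort(seed=s)).vertex_age
              for s in range(100)]
        assert all(v is not None for v in vs)
        assert abs(np.mean(vs) - 45.0) < 5.0


class TestDecadeAnova:
    def test_matches_sum_of_squares_oracle(self):
        groups = {
            "20s": [1.2, 1.3, 1.25, 1.4],
            "40s": [1.5, 1.6, 1.55],
            "70s": [1.1, 1.0, 1.15, 1.05, 1.2],
        }
        rows = []
        for dec, vals in groups.items():
            age = int(dec[:2]) + 1
            rows += [{"subject_id": f"{dec}{i}", "age": age,
                      "index_obs_A": v, "index_obs_B": v}
                     for i, v in enumerate(vals)]
        t = d.CohortTable.from_records(pd.DataFrame(rows))
        res = d.decade_anova(t)
        assert res.f_statistic == pytest.approx(
            anova_f_oracle(list(groups.values())), abs=1e-12
        )
        assert len(res.pairwise) == 3  # C(3,2)

    def test_zero_within_group_variance_max_f(self):
        t = _table_from_pairs([21, 22, 71, 72], [1.0, 1.0, 2.0, 2.0],
                              [1.0, 1.0, 2.0, 2.0])
        res = d.decade_anova(t)
        assert np.isinf(res.f_statistic) or res.f_statistic > 1e10
        assert bool(res.pairwise["reject"].iloc[0])

    def test_insufficient_groups_raise(self):
        t = _table_from_pairs([21, 22, 23], [1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        with pytest.raises(ValueError, match=">= 2 decade groups"):
            d.decade_anova(t)

    def test_tukey_significant_set_invariant_under_relabeling(self):
        """The set of significant pairs must not depend on group label
        ordering."""
        t = d.generate_cohort(seed=5)
        res = d.decade_anova(t)
        relabel = {f"{g}s": f"grp{(g // 10 + 3) % 8}" for g in range(10, 90, 10)}
        df2 = t.df.copy()
        df2["decade"] = df2["decade"].map(relabel)
        t2 = d.CohortTable(df=df2)

        def sigset(res, mapping=None):
            out = set()
            for _, row in res.pairwise.iterrows():
                a, b = str(row["group1"]), str(row["group2"])
                if mapping:
                    a, b = mapping[a], mapping[b]
                if row["reject"]:
                    out.add(frozenset((a, b)))
            return out

        assert sigset(res, relabel) == sigset(d.decade_anova(t2))

    def test_boxplot_quartiles_type7(self):
        vals = list(range(1, 10))  # {1..9}
        t = _table_from_pairs([20 + i for i in range(9)] + [71, 72],
                              vals + [5, 5], vals + [5, 5])
        res = d.decade_anova(t)
        g20 = next(g for g in res.groups if g.label == "20s")
        assert g20.median == 5.0
        assert g20.q1 == 3.0 and g20.q3 == 7.0  # linear interpolation
        assert g20.outliers == []

    def test_outliers_by_iqr_rule(self):
        vals = [1.0, 1.01, 1.02, 1.03, 1.04, 5.0]
        t = _table_from_pairs([20, 21, 22, 23, 24, 25] + [71, 72],
                              vals + [1.0, 1.0], vals + [1.0, 1.0])
        res = d.decade_anova(t)
        g20 = next(g for g in res.groups if g.label == "20s")
        assert g20.outliers == [5.0]
        assert g20.whisker_hi < 5.0

    def test_null_calibration(self):
        """Type-I error: with no decade effect the ANOVA rejects at ~alpha.
        2000 simulated null cohorts; rejection fraction within [0.03, 0.07]."""
        spec = d.null_cohort_spec()
        rej = sum(
            d.decade_anova(d.generate_cohort(spec, seed=s), posthoc=False).p_value
            < 0.05
            for s in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07


class TestPlotCohort:
    def test_plot_data_serializes_computed_curves(self, tmp_path):
        t = d.generate_cohort(seed=9)
        lin, sub, quad = d.linear_fit(t), d.linear_fit(t, 40), d.quadratic_fit(t)
        an = d.decade_anova(t)
        import json

        pd1 = d.plot_cohort(t, lin, sub, quad, an, out_dir=tmp_path, stem="a")
        pd2 = d.plot_cohort(t, lin, sub, quad, an, out_dir=tmp_path, stem="b")
        for k in ("linear", "subgroup", "quadratic", "boxplot", "scatter"):
            assert json.dumps(pd1[k], sort_keys=True) == json.dumps(
                pd2[k], sort_keys=True
            )
        assert (tmp_path / "a_age_index.png").exists()
        assert (tmp_path / "a_decade_boxplot.png").exists()

    def test_missing_fits_omitted(self, tmp_path):
        t = d.generate_cohort(seed=9)
        out = d.plot_cohort(t, linear=d.linear_fit(t), out_dir=tmp_path)
        assert "quadratic" not in out
        assert out["files"]["boxplot"] is None
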