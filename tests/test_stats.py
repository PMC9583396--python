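"""Group-statistics layer: t-test, Box-Cox, Type-III ANCOVA and partial
Spearman, each against an independent oracle (closed form, scipy/pingouin, or
a hand-rolled balanced two-way ANOVA)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from imcoh import (
    ancova_limb_by_pair,
    boxcox,
    demographics_summary,
    load_stroke_cohort,
    partial_spearman,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0) and r.effect == 0.0

    def test_hand_computed_pooled_formula(self):
        # pooled sp^2 = 5/3, t = -2/sqrt(5/6) = -2.191, d = -2/sqrt(5/3) = -1.549
        r = two_sample_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert r.statistic == pytest.approx(-2.191, abs=1e-3)
        assert r.df == 6
        assert r.effect == pytest.approx(-1.549, abs=1e-3)
        t_scipy, p_scipy = sps.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=True)
        assert r.statistic == pytest.approx(float(t_scipy))
        assert r.p == pytest.approx(float(p_scipy))

    def test_permutation_oracle_agreement(self, rng):
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        r = two_sample_t(a, b)
        pooled = np.r_[a, b]
        observed = abs(a.mean() - b.mean())
        count = 0
        reps = 2000
        for _ in range(reps):
            rng.shuffle(pooled)
            count += abs(pooled[:12].mean() - pooled[12:].mean()) >= observed
        assert r.p == pytest.approx(count / reps, abs=0.03)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(500):
            ps.append(two_sample_t(rng.normal(size=10), rng.normal(size=10)).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBoxCox:
    def test_lambda_one_is_shift(self):
        y = np.array([1.0, 2.0, 5.0])
        assert np.allclose(sps.boxcox(y, lmbda=1.0), y - 1.0)

    def test_lognormal_sample_gives_lambda_near_zero(self, rng):
        y = np.exp(rng.standard_normal(5000))
        _, lam, off = boxcox(y)
        assert off == 0.0
        assert -0.15 < lam < 0.15

    def test_normalish_sample_gives_lambda_near_one(self, rng):
        y = rng.normal(10.0, 1.0, 5000)
        _, lam, _ = boxcox(y)
        assert 0.6 < lam < 1.4

    def test_zero_values_get_offset(self):
        y = np.array([0.0, 0.2, 0.4, 0.9, 1.4])
        transformed, lam, off = boxcox(y)
        assert off == pytest.approx(0.1)
        assert np.all(np.isfinite(transformed))

    def test_rank_preservation(self, rng):
        y = rng.lognormal(size=200)
        transformed, _, _ = boxcox(y)
        assert np.array_equal(np.argsort(y), np.argsort(transformed))

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox([0.0, 0.0, 0.0])


def metrics_table(rng, n=12, limb_shift=0.0, limbs=("paretic", "dominant")):
    rows = []
    for limb in limbs:
        for s in range(n):
            for pair in ("BB-BR", "TB-BR"):
                y = rng.lognormal(0.0, 1.0) + (limb_shift if limb == limbs[0] else 0.0)
                rows.append(
                    dict(
                        subject=f"{limb[:3]}{s}", limb=limb, muscle_pair=pair,
                        imc_volume=y,
                        mean_angle=rng.normal(120, 10),
                        mean_velocity=rng.normal(100, 20),
                        age=rng.uniform(35, 75),
                        cocontraction=rng.normal(25, 8),
                    )
                )
    return pd.DataFrame(rows)


class TestAncova:
    def test_unbalanced_design_rejected(self, rng):
        tab = metrics_table(rng)
        with pytest.raises(ValueError, match="unbalanced"):
            ancova_limb_by_pair(tab.iloc[:-1], ("paretic", "dominant"))

    def test_missing_limb_rejected(self, rng):
        tab = metrics_table(rng)
        with pytest.raises(ValueError):
            ancova_limb_by_pair(tab, ("paretic", "non-paretic"))

    def test_reports_all_terms_with_partial_eta_squared(self, rng):
        res = ancova_limb_by_pair(metrics_table(rng), ("paretic", "dominant"))
        expected = {
            "limb", "muscle_pair", "limb:muscle_pair",
            "mean_angle", "mean_velocity", "age", "cocontraction",
        }
        assert set(res) == expected
        for s in res.values():
            assert 0.0 <= s.p <= 1.0
            assert 0.0 <= s.effect <= 1.0
            assert s.extra["alpha"] == 0.017

    def test_covariate_free_fit_matches_manual_two_way_anova(self, rng):
        # balanced 2x2: Type-III F values equal the textbook cell-mean ANOVA
        tab = metrics_table(rng, n=8, limb_shift=1.0)
        res = ancova_limb_by_pair(
            tab, ("paretic", "dominant"), transform=False, covariates=()
        )
        y = tab["imc_volume"].to_numpy()
        a = (tab["limb"] == "paretic").to_numpy()
        b = (tab["muscle_pair"] == "BB-BR").to_numpy()
        n_cell = y.size / 4
        grand = y.mean()
        ss_a = 2 * n_cell * sum((y[a == i].mean() - grand) ** 2 for i in (0, 1))
        ss_b = 2 * n_cell * sum((y[b == i].mean() - grand) ** 2 for i in (0, 1))
        cells = {(i, j): y[(a == i) & (b == j)].mean() for i in (0, 1) for j in (0, 1)}
        ss_ab = n_cell * sum(
            (cells[i, j] - y[a == i].mean() - y[b == j].mean() + grand) ** 2
            for i in (0, 1) for j in (0, 1)
        )
        ss_err = sum((y[(a == i) & (b == j)] - cells[i, j]) ** 2 for i in (0, 1) for j in (0, 1)).sum()
        df_err = y.size - 4
        assert res["limb"].statistic == pytest.approx(ss_a / 1 / (ss_err / df_err), rel=1e-8)
        assert res["muscle_pair"].statistic == pytest.approx(ss_b / (ss_err / df_err), rel=1e-8)
        assert res["limb:muscle_pair"].statistic == pytest.approx(ss_ab / (ss_err / df_err), rel=1e-8)

    def test_planted_limb_shift_detected(self, rng):
        hits = 0
        for _ in range(20):
            tab = metrics_table(rng, n=24, limb_shift=2.0)
            res = ancova_limb_by_pair(tab, ("paretic", "dominant"))
            hits += res["limb"].p < 0.017
        assert hits >= 16  # >80 % power for a planted 1-SD-scale shift


class TestPartialSpearman:
    def test_exact_antitone_gives_minus_one(self, rng):
        x = rng.uniform(size=30)
        z = rng.uniform(size=(30, 2))
        r = partial_spearman(x, -x, z)
        assert r.statistic == pytest.approx(-1.0)
        assert r.p < 1e-6

    def test_zero_covariates_equals_plain_spearman(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert r.statistic == pytest.approx(float(rho), abs=1e-12)
        assert r.p == pytest.approx(float(p), rel=0.05)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ours = partial_spearman(x, y, z[:, None])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_confounder_removed(self, rng):
        rhos = []
        for _ in range(10):
            z = rng.normal(size=500)
            x = z + rng.normal(size=500)
            y = z + rng.normal(size=500)
            rhos.append(abs(partial_spearman(x, y, z[:, None]).statistic))
        assert np.mean(rhos) < 0.1

    def test_outlier_rule_drops_flagged_points(self, rng):
        # residuals come from the covariate regressions, so the rule needs a
        # covariate that tracks both variables tightly
        n = 40
        z = rng.normal(size=n)
        x = z + 0.1 * rng.normal(size=n)
        y = z + 0.1 * rng.normal(size=n)
        y[0] += 8.0  # gross outlier in the y-model residuals
        with_out = partial_spearman(x, y, z[:, None], drop_outliers=False)
        without = partial_spearman(x, y, z[:, None], drop_outliers=True)
        assert 0 in without.extra["outliers"]
        assert without.extra["n_used"] < n

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(20), np.arange(20.0))

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_spearman(np.arange(5.0), np.arange(5.0), rng.normal(size=(5, 2)))


class TestDemographics:
    def test_cohort_columns_summary(self):
        cohort = load_stroke_cohort()
        summary = demographics_summary(cohort, ["age_years", "emnsa", "fugl_meyer"])
        assert summary.loc["emnsa", "n"] == 24
        assert summary.loc["emnsa", "mean"] == pytest.approx(48.875)
        assert summary.loc["emnsa", "sd"] == pytest.approx(14.1646, abs=1e-3)

    def test_single_value_column_rejected(self):
        with pytest.raises(ValueError, match="single value"):
            demographics_summary(pd.DataFrame({"x": [1.0]}))

    def test_empty_numeric_selection_rejected(self):
        with pytest.raises(ValueError):
            demographics_summary(pd.DataFrame({"s": ["a", "b"]}))
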