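import numpy as np
import pandas as pd
import pytest

import steatoquant as sq
from steatoquant.agreement import UndefinedStatisticError

from oracles import (
    bland_altman_oracle,
    pearson_oracle,
    rmse_oracle,
    spearman_oracle,
    weighted_kappa_oracle,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        pr = sq.pearson(x, 3 * x - 7)
        assert pr.r == pytest.approx(1.0) and pr.r2 == pytest.approx(1.0)

    def test_r2_is_r_squared_to_machine_precision(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        pr = sq.pearson(x, y)
        assert pr.r2 == pr.r**2

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=100)
            y = 0.6 * x + 0.8 * rng.normal(size=100)
            assert sq.pearson(x, y).r == pytest.approx(
                pearson_oracle(list(x), list(y)), abs=1e-12
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r0 = sq.pearson(x, y).r
        assert sq.pearson(2.5 * x + 3, y).r == pytest.approx(r0, abs=1e-12)
        assert sq.pearson(x, 0.1 * y - 9).r == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sq.pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = 0.7 * x + rng.normal(size=60)
        pr = sq.pearson(x, y)
        assert pr.ci95[0] < pr.r < pr.ci95[1]


class TestSpearman:
    def test_strictly_decreasing_is_minus_one(self):
        x = np.arange(8.0)
        rho, _ = sq.spearman(x, -(x**3) - 1)
        assert rho == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0, _ = sq.spearman(x, y)
        r1, _ = sq.spearman(np.exp(x), y)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_all_tied_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sq.spearman([2, 2, 2, 2], [1, 2, 3, 4])

    def test_tied_data_matches_midrank_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 5, 30).astype(float)
            y = rng.integers(0, 5, 30).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, _ = sq.spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestRmse:
    def test_identical_is_zero_and_offset_is_offset(self):
        x = np.arange(10.0)
        assert sq.rmse(x, x) == 0.0
        assert sq.rmse(x + 3, x) == pytest.approx(3.0, abs=1e-12)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 40, 50)
        y = rng.uniform(0, 40, 50)
        assert sq.rmse(x, y) == pytest.approx(rmse_oracle(x, y), abs=1e-12)


class TestWeightedKappa:
    BINS = list(range(7))

    def test_identical_raters_give_kappa_one(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 7, 60)
        k, _ = sq.weighted_kappa(a, a, bins=self.BINS)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_weight_formula_endpoints(self):
        w = sq.agreement.quadratic_weights(7)
        assert w[0, 6] == 1.0 and w[0, 0] == 0.0
        assert w[2, 4] == pytest.approx(4 / 36)

    def test_symmetry_in_raters(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 7, 50)
        b = rng.integers(0, 7, 50)
        assert sq.weighted_kappa(a, b, bins=self.BINS)[0] == pytest.approx(
            sq.weighted_kappa(b, a, bins=self.BINS)[0], abs=1e-12
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.integers(0, 7, 40)
            b = np.clip(a + rng.integers(-3, 4, 40), 0, 6)
            if np.unique(a).size < 2 or np.unique(b).size < 2:
                continue
            k, _ = sq.weighted_kappa(a, b, bins=self.BINS)
            assert k == pytest.approx(
                weighted_kappa_oracle(list(a), list(b), 7), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(10)
        a = rng.integers(0, 7, 80)
        b = np.clip(a + rng.integers(-2, 3, 80), 0, 6)
        k, _ = sq.weighted_kappa(a, b, bins=self.BINS)
        assert k == pytest.approx(
            sk.cohen_kappa_score(a, b, weights="quadratic", labels=self.BINS),
            abs=1e-12,
        )

    def test_constant_rater_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            sq.weighted_kappa([1, 1, 1, 1], [0, 1, 2, 3], bins=self.BINS)

    def test_category_shift_decreases_kappa(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 5, 100)
        b = np.clip(a + rng.integers(-1, 2, 100), 0, 6)
        k0, _ = sq.weighted_kappa(a, b, bins=self.BINS)
        k1, _ = sq.weighted_kappa(a, np.clip(b + 1, 0, 6), bins=self.BINS)
        assert k1 < k0

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 7, 48)
        b = np.clip(a + rng.integers(-2, 3, 48), 0, 6)
        k1, ci1 = sq.weighted_kappa(a, b, bins=self.BINS, ci_method="bootstrap",
                                    seed=5)
        k2, ci2 = sq.weighted_kappa(a, b, bins=self.BINS, ci_method="bootstrap",
                                    seed=5)
        assert ci1 == ci2 and ci1[0] <= k1 <= ci1[1]


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value,band",
        [(0.595, "moderate"), (0.729, "substantial"), (0.205, "fair"),
         (0.1, "slight"), (0.95, "almost perfect"),
         (-0.2, "poor (less than chance)")],
    )
    def test_landis_koch_bands(self, value, band):
        assert sq.interpret_kappa(value) == band

    @pytest.mark.parametrize("bad", [-1.5, 1.1])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            sq.interpret_kappa(bad)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        bias, lo, hi, _ = sq.bland_altman(x, x)
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.arange(10.0)
        bias, lo, hi, _ = sq.bland_altman(x + 3, x)
        assert bias == pytest.approx(3.0) and lo == pytest.approx(3.0) \
            and hi == pytest.approx(3.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 40, 60)
        y = x + rng.normal(0, 3, 60)
        got = sq.bland_altman(x, y)[:3]
        want = bland_altman_oracle(x, y)
        assert got == pytest.approx(want, abs=1e-12)

    def test_loa_brackets_bias(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 40, 30)
        y = x + rng.normal(0, 2, 30)
        bias, lo, hi, table = sq.bland_altman(x, y)
        assert lo <= bias <= hi and len(table) == 30


class TestToleranceAndRange:
    def test_equal_scores_rate_one(self):
        ai = np.array([5.0, 10.0, 20.0])
        ratings = ai[:, None]
        rate, n_used, n_excl = sq.tolerance_rate(ai, ratings)
        assert rate == 1.0 and n_used == 3 and n_excl == 0

    def test_boundary_difference_of_five_counts_as_within(self):
        ai = np.array([10.0, 20.0])
        ratings = np.array([[5.0], [25.0]])
        rate, _, _ = sq.tolerance_rate(ai, ratings)
        assert rate == 1.0

    def test_missing_rater_cases_excluded(self):
        ai = np.array([10.0, 20.0, 30.0])
        ratings = np.array([[10.0, np.nan], [np.nan, np.nan], [28.0, 30.0]])
        rate, n_used, n_excl = sq.tolerance_rate(ai, ratings)
        assert n_used == 2 and n_excl == 1 and rate == 1.0

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(15)
        ai = rng.uniform(0, 40, 50)
        ratings = ai[:, None] + rng.normal(0, 5, (50, 3))
        rate, n_used, _ = sq.tolerance_rate(ai, ratings)
        means = ratings.mean(axis=1)
        expect = sum(abs(a - m) <= 5.0 for a, m in zip(ai, means)) / 50
        assert rate == pytest.approx(expect, abs=1e-12) and n_used == 50

    def test_range_classification_definition(self):
        ai = np.array([9.0, 3.0, 6.0, 4.0])
        ratings = np.array([[4.0, 8.0]] * 4)
        counts = sq.range_classification(ai, ratings)
        assert counts == {"higher": 1, "lower": 1, "within": 2}

    def test_single_rater_equality_is_within(self):
        counts = sq.range_classification(np.array([7.0]), np.array([[7.0]]))
        assert counts == {"higher": 0, "lower": 0, "within": 1}

    def test_range_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(16)
        ai = rng.uniform(0, 30, 40)
        ratings = rng.uniform(0, 30, (40, 3))
        counts = sq.range_classification(ai, ratings)
        expect = {"higher": 0, "lower": 0, "within": 0}
        for a, row in zip(ai, ratings):
            if a > max(row):
                expect["higher"] += 1
            elif a < min(row):
                expect["lower"] += 1
            else:
                expect["within"] += 1
        assert counts == expect


class TestNormality:
    def test_normal_data_rarely_rejected(self):
        rng = np.random.default_rng(17)
        passes = sum(
            sq.normality_test(rng.normal(size=200))[1] > 0.05 for _ in range(100)
        )
        assert passes >= 90

    def test_lognormal_grossly_rejected(self):
        rng = np.random.default_rng(18)
        _, p = sq.normality_test(rng.lognormal(0, 1, 100))
        assert p < 0.001

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sq.normality_test(np.ones(20))

    def test_sample_size_domain(self):
        with pytest.raises(ValueError):
            sq.normality_test([1.0, 2.0])


class TestVarianceReduction:
    def test_three_rater_factor_rounds_to_058(self):
        assert round(sq.variance_reduction_factor(3), 2) == 0.58

    def test_simulated_sd_reduction_matches_sqrt_rule(self):
        rng = np.random.default_rng(19)
        truth = rng.uniform(0, 30, 1000)
        raters = truth[:, None] + rng.normal(0, 4.0, (1000, 3))
        sd_single = np.std(raters[:, 0] - truth)
        sd_mean = np.std(raters.mean(axis=1) - truth)
        assert sd_mean / sd_single == pytest.approx(
            sq.variance_reduction_factor(3), rel=0.10
        )


class TestReportAssembly:
    def _wide(self):
        rng = np.random.default_rng(20)
        truth = rng.uniform(0, 35, 48)
        data = {
            "AI": np.clip(truth + rng.normal(0, 3, 48), 0, 100),
            "P1": np.clip(truth + rng.normal(0, 4, 48), 0, 100),
            "P2": np.clip(truth + rng.normal(0, 4, 48), 0, 100),
        }
        return pd.DataFrame(data, index=[f"case{i}" for i in range(48)])

    def test_report_values_equal_direct_function_calls(self):
        wide = self._wide()
        report = sq.agreement_report(wide, ai_rater="AI")
        x = wide["AI"].to_numpy()
        y = wide["P1"].to_numpy()
        pair = report["pairwise"]["AI vs P1"]
        assert pair["pearson_r"] == pytest.approx(sq.pearson(x, y).r, abs=1e-12)
        assert pair["rmse"] == pytest.approx(sq.rmse(x, y), abs=1e-12)
        ka, _ = sq.weighted_kappa(
            [sq.bin_category(v) for v in x], [sq.bin_category(v) for v in y]
        )
        assert pair["weighted_kappa"] == pytest.approx(ka, abs=1e-12)
        mean_others = wide[["P1", "P2"]].mean(axis=1).to_numpy()
        assert report["ai_vs_mean"]["pearson_r"] == pytest.approx(
            sq.pearson(x, mean_others).r, abs=1e-12
        )

    def test_pairwise_deletion_with_missing_raters(self):
        wide = self._wide()
        wide.loc[wide.index[:20], "P2"] = np.nan
        report = sq.agreement_report(wide, ai_rater="AI")
        assert report["pairwise"]["P1 vs P2"]["n"] == 28
        assert report["pairwise"]["AI vs P1"]["n"] == 48

    def test_ratings_wide_validation(self):
        bad = pd.DataFrame({"case_id": ["a"], "rater": ["P1"],
                            "score_pct": ["oops"]})
        with pytest.raises(ValueError, match="non-numeric"):
            sq.ratings_wide(bad)
        out_of_range = pd.DataFrame({"case_id": ["a"], "rater": ["P1"],
                                     "score_pct": [120.0]})
        with pytest.raises(ValueError, match="within"):
            sq.ratings_wide(out_of_range)
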