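"""Sequential effect, Pearson regressions and the slope-equality test."""

import numpy as np
import pytest
from scipy import stats as sps

from stopbayes import (
    bonferroni_threshold,
    pearson_regression,
    sequential_effect,
    slope_difference_test,
)
from stopbayes.stats import InsufficientDataError, UndefinedCorrelationError


class TestSequentialEffect:
    def test_perfect_linear_coupling(self):
        pstop = np.linspace(0.1, 0.5, 50)
        eff = sequential_effect(pstop, 500.0 + 200.0 * pstop)
        assert eff.r == pytest.approx(1.0)
        assert eff.n_trials == 50

    def test_matches_textbook_pearson_formula(self, rng):
        x = rng.random(80)
        y = rng.normal(size=80)
        eff = sequential_effect(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert eff.r == pytest.approx(manual, abs=1e-14)

    def test_null_coupling_small_r(self, rng):
        x, y = rng.random(300), rng.normal(size=300)
        assert abs(sequential_effect(x, y).r) < 0.15

    def test_mask_selects_pairs(self):
        pstop = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        rt = np.array([500.0, np.nan, 600.0, 650.0, 700.0])
        eff = sequential_effect(pstop, rt, include_mask=[True, False, True, True, True])
        assert eff.n_trials == 4 and eff.r > 0.99

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            sequential_effect([0.2, 0.3], [500.0, 600.0])
        with pytest.raises(UndefinedCorrelationError):
            sequential_effect([0.25] * 10, np.arange(10.0))


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = pearson_regression(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_r_squared_identity(self, rng):
        x = rng.normal(size=120)
        y = 0.5 * x + rng.normal(size=120)
        res = pearson_regression(x, y)
        assert res.r**2 == pytest.approx(res.slope**2 * x.var() / y.var(), abs=1e-12)

    def test_null_r_bound_at_n149(self, rng):
        x, y = rng.standard_normal(149), rng.standard_normal(149)
        assert abs(pearson_regression(x, y).r) < 0.21

    def test_partial_correlation_matches_residual_oracle(self, rng):
        """Partial r given a covariate equals the correlation of the two
        residual vectors after regressing the covariate out of each."""
        n = 100
        c = rng.normal(size=n)
        x = 0.7 * c + rng.normal(size=n)
        y = 0.5 * c + 0.3 * x + rng.normal(size=n)
        res = pearson_regression(x, y, covariates=c)

        def resid(v):
            D = np.column_stack([np.ones(n), c])
            return v - D @ np.linalg.lstsq(D, v, rcond=None)[0]

        oracle = sps.pearsonr(resid(x), resid(y)).statistic
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_collinear_covariate_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(np.linalg.LinAlgError):
            pearson_regression(x, rng.normal(size=30), covariates=2.0 * x)


class TestSlopeDifference:
    def test_identical_outcomes(self, rng):
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(size=50)
        t, p = slope_difference_test(x, y, x, y)
        assert (t, p) == (0.0, 1.0)

    def test_null_calibration(self):
        """Equal true slopes: the paired test's p-value is uniform."""
        rng = np.random.default_rng(42)
        n, reps = 149, 1000
        pvals = np.empty(reps)
        for i in range(reps):
            x = rng.normal(size=n)
            y1 = 1.0 * x + rng.normal(size=n)
            y2 = 1.0 * x + rng.normal(size=n)
            pvals[i] = slope_difference_test(x, y1, y2=y2, x2=x)[1]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_three_pooled_ses(self):
        rng = np.random.default_rng(43)
        n, reps = 149, 200
        # slope SE of the difference regression: sd(e1-e2)/(sqrt(n) sd_x)
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            se_pooled = np.sqrt(2.0) / (np.sqrt(n) * x.std())
            y1 = (1.0 + 3.0 * se_pooled) * x + rng.normal(size=n)
            y2 = 1.0 * x + rng.normal(size=n)
            hits += slope_difference_test(x, y1, x, y2)[1] < 0.05
        assert hits / reps >= 0.80

    def test_unpaired_variant(self, rng):
        x1, x2 = rng.normal(size=80), rng.normal(size=70)
        y1 = 2.0 * x1 + rng.normal(size=80)
        y2 = 2.0 * x2 + rng.normal(size=70)
        t, p = slope_difference_test(x1, y1, x2, y2, paired=False)
        assert abs(t) < 3.0 and 0.0 <= p <= 1.0

    def test_mismatched_pairing_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="pair"):
            slope_difference_test(x, x + 1.0, x[:20], x[:20] + 1.0)


def test_bonferroni_helper():
    assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
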