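"""One-sided Spearman inference, R², and the percentile bootstrap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import virhost as vh
from virhost.errors import UndefinedMetricError, ValidationError
from virhost.stats import spearman_one_sided, spearman_rho


class TestSpearman:
    def test_perfect_antitone_rho(self):
        res = spearman_one_sided([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], "less")
        assert res.rho == pytest.approx(-1.0)

    def test_exact_p_for_antitone_n5_is_one_over_120(self):
        res = spearman_one_sided([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], "less", method="exact")
        assert res.p_one_sided == pytest.approx(1 / 120)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedMetricError):
            spearman_one_sided([1, 2, 3], [2, 2, 2], "less")

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            spearman_one_sided([1, 2], [2, 1], "less")

    def test_frozen_reference_values_without_ties(self):
        """rho and p agree with R's cor.test to printed precision (frozen)."""
        x = [2.1, 0.5, 3.3, 1.7, 4.2, 2.8, 0.9, 3.9]
        y = [5.0, 6.2, 2.1, 4.4, 1.0, 3.3, 6.8, 2.5]
        t_res = spearman_one_sided(x, y, "less", method="t")
        e_res = spearman_one_sided(x, y, "less", method="exact")
        assert t_res.rho == pytest.approx(-0.928571428571, abs=1e-10)
        assert t_res.p_one_sided == pytest.approx(0.000431484091, abs=1e-10)
        assert e_res.p_one_sided == pytest.approx(0.00111607143, abs=1e-9)

    def test_frozen_reference_values_with_ties(self):
        """Average-rank tie handling matches R's cor.test t approximation (frozen)."""
        res = spearman_one_sided([1, 2, 2, 3, 4, 5, 5], [7, 6, 5, 5, 3, 2, 1], "less")
        assert res.rho == pytest.approx(-0.963343294486, abs=1e-10)
        assert res.p_one_sided == pytest.approx(0.000242228468, abs=1e-10)

    def test_na_pairs_removed_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [6.0, 5.0, 4.0, np.nan, 2.0, 1.0]
        res = spearman_one_sided(x, y, "less")
        assert res.n == 4
        assert res.rho == pytest.approx(-1.0)

    def test_agrees_with_independent_library_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            for alt in ("less", "greater"):
                mine = spearman_one_sided(x, y, alt)
                ref_rho, ref_p = sps.spearmanr(x, y, alternative=alt)
                assert mine.rho == pytest.approx(ref_rho, abs=1e-12)
                assert mine.p_one_sided == pytest.approx(ref_p, rel=1e-9)

    @given(st.integers(min_value=0, max_value=200))
    def test_symmetry_and_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x), abs=1e-12)
        assert spearman_rho(x, -y) == pytest.approx(-spearman_rho(x, y), abs=1e-12)

    @given(st.integers(min_value=0, max_value=100))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(rho, abs=1e-12)

    @pytest.mark.parametrize("n", [7, 8, 9])
    def test_exact_and_t_approximation_agree(self, n):
        """Calibration: t-approximate and exact permutation p within 0.02."""
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            p_t = spearman_one_sided(x, y, "less", method="t").p_one_sided
            p_e = spearman_one_sided(x, y, "less", method="exact").p_one_sided
            assert abs(p_t - p_e) < 0.02


class TestRSquared:
    def test_collinear_points_give_one(self):
        assert vh.r_squared([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    def test_hand_computed_least_squares(self):
        # x=[0,1,2], y=[0,1,1]: slope 1/2, intercept 1/6, SSres = 1/6, SStot = 2/3
        assert vh.r_squared([0, 1, 2], [0, 1, 1]) == pytest.approx(0.75)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert vh.r_squared(x, y) < 0.01

    @given(st.integers(min_value=0, max_value=100))
    def test_equals_squared_pearson_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.3 * x
        pearson = float(np.corrcoef(x, y)[0, 1])
        assert vh.r_squared(x, y) == pytest.approx(pearson**2, abs=1e-12)
        assert vh.r_squared(y, x) == pytest.approx(vh.r_squared(x, y), abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(UndefinedMetricError):
            vh.r_squared([1, 1, 1], [1, 2, 3])


class TestBootstrap:
    def test_antitone_data_ci_stays_negative(self):
        x = np.arange(10.0)
        y = -x
        lo, hi = vh.bootstrap_corr_ci(x, y, n_boot=500, seed=0)
        assert hi <= 0

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert vh.bootstrap_corr_ci(x, y, seed=3) == vh.bootstrap_corr_ci(x, y, seed=3)

    def test_nominal_coverage_under_independence(self):
        """A 90% CI on independent data contains 0 in >= 85% of repetitions."""
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            x, y = rng.normal(size=100), rng.normal(size=100)
            lo, hi = vh.bootstrap_corr_ci(x, y, n_boot=200, ci_level=0.90, seed=seed)
            hits += lo <= 0 <= hi
        assert hits / reps >= 0.85

    def test_mostly_degenerate_resamples_abort(self):
        # constancy of a resample requires missing one endpoint; here it is likely
        x = [1.0, 1.0, 1.0, 1.0, 2.0]
        y = [2.0, 1.0, 1.0, 1.0, 1.0]
        with pytest.raises(ValidationError):
            vh.bootstrap_corr_ci(x, y, n_boot=400, seed=0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            vh.bootstrap_corr_ci([1, 2, 3], [3, 2, 1], seed=0)


class TestCorrelate:
    def test_full_record_fields(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = -x + rng.normal(scale=0.5, size=25)
        res = vh.correlate(x, y, alternative="less", n_boot=300, seed=1)
        assert -1 <= res.ci_low <= res.ci_high <= 1
        assert res.rho < 0 and res.p_one_sided < 0.05
        assert 0 <= res.r_squared <= 1
        assert res.n == 25 and res.n_boot == 300
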