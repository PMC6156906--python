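"""Unit and oracle tests for the statistical primitives."""

import math

import numpy as np
import pytest
from scipy import optimize
from scipy import stats as sps
from scipy.special import comb

from prescriptome.stats import (
    ContingencyTable2x2,
    PriorSpec,
    bh_adjust,
    fisher_exact_2x2,
    fit_bayes_logistic,
    format_p,
    haldane_odds_ratio,
    hypergeom_tail,
    penalized_loglik,
    wald_or_ci,
    welch_t_test,
    wilson_interval,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_enum(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum hypergeometric point probabilities
    <= that of the observed table (point-probability rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1, exact=True)
    probs = {
        x: comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def hypergeom_upper_enum(N, m, n, k):
    denom = comb(N, n, exact=True)
    return sum(
        comb(m, x, exact=True) * comb(N - m, n - x, exact=True) / denom
        for x in range(k, min(m, n) + 1)
    )


def cauchy_objective(y, X, beta, scales):
    eta = X @ beta
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return ll + sum(sps.cauchy.logpdf(b, scale=s) for b, s in zip(beta, scales))


# ---------------------------------------------------------------------------
# penalized logistic regression
# ---------------------------------------------------------------------------


class TestBayesLogistic:
    def test_null_slope_near_one(self, rng):
        """Outcome independent of a binary predictor: OR close to 1 at n=1000."""
        n = 1000
        x = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_bayes_logistic(y, X, term_names=["intercept", "x"])
        or_, *_ = wald_or_ci(fit, "x")
        assert fit.converged
        assert 0.8 <= or_ <= 1.25

    def test_complete_separation_is_finite(self):
        """A predictor present only in the 3 cases of a 20-patient toy: the
        posterior mode and its SE stay finite under the Cauchy prior."""
        y = np.array([1, 1, 1] + [0] * 17, dtype=float)
        x = np.array([1, 1, 1] + [0] * 17, dtype=float)
        X = np.column_stack([np.ones(20), x])
        fit = fit_bayes_logistic(y, X)
        assert fit.converged
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(np.isfinite(fit.standard_errors))
        assert np.all(fit.standard_errors > 0)

    def test_mode_matches_independent_optimizer(self, rng):
        """Newton's mode matches a derivative-free scipy oracle on random
        small designs to |delta penalized log-lik| <= 1e-6."""
        prior = PriorSpec()
        scales = [10.0, 2.5, 2.5]
        for _ in range(10):
            n = 30
            X = np.column_stack([np.ones(n), rng.random(n) < 0.3, rng.normal(size=n)])
            y = (rng.random(n) < 0.4).astype(float)
            fit = fit_bayes_logistic(y, X, prior, standardize=False)
            ours = cauchy_objective(y, X, fit.coefficients, scales)
            res = optimize.minimize(
                lambda b: -cauchy_objective(y, X, b, scales),
                np.zeros(3),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert ours >= -res.fun - 1e-6

    def test_flat_prior_reproduces_mle(self, rng):
        """Flat prior equals classical ML logistic (statsmodels IRLS) within
        1e-5 on non-separated data."""
        import statsmodels.api as sm

        n = 400
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.normal(size=n)
        eta = -1.0 + 0.8 * x1 + 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        fit = fit_bayes_logistic(y, X, PriorSpec(family="flat"))
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-5)
        assert np.allclose(fit.standard_errors, ref.bse, atol=1e-4)

    def test_standardized_and_raw_flat_fits_agree(self, rng):
        """With a flat prior, the internal standardization must not change
        the reported (original-scale) coefficients."""
        n = 300
        X = np.column_stack([np.ones(n), rng.random(n) < 0.4, 30 + 10 * rng.random(n)])
        y = (rng.random(n) < 0.3).astype(float)
        f1 = fit_bayes_logistic(y, X, PriorSpec(family="flat"), standardize=True)
        f2 = fit_bayes_logistic(y, X, PriorSpec(family="flat"), standardize=False)
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-5)

    def test_input_validation(self):
        y = np.array([0.0, 1.0, 2.0])
        X = np.ones((3, 1))
        with pytest.raises(ValueError):
            fit_bayes_logistic(y, X)
        with pytest.raises(ValueError):
            fit_bayes_logistic(np.zeros(3), np.zeros((3, 1)))

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(family="gaussian")
        with pytest.raises(ValueError):
            PriorSpec(scale_coeff=-1)


class TestWaldOrCi:
    def test_closed_form_unit_normal(self):
        fit_like = fit_bayes_logistic(
            np.array([0.0, 1.0]), np.ones((2, 1))
        )  # placeholder shape
        fit_like.coefficients = np.array([0.0])
        fit_like.standard_errors = np.array([1.0])
        fit_like.term_names = ("x",)
        or_, lo, hi, p = wald_or_ci(fit_like, "x")
        assert or_ == 1.0
        assert lo == pytest.approx(math.exp(-1.959964), abs=1e-4)
        assert hi == pytest.approx(math.exp(1.959964), abs=1e-4)
        assert lo == pytest.approx(0.1409, abs=1e-4)
        assert hi == pytest.approx(7.0991, abs=1e-3)
        assert p == pytest.approx(1.0)

    def test_point_or_is_exp_beta_and_ordering(self):
        fit = fit_bayes_logistic(np.array([0.0, 1.0, 1.0, 0.0]), np.ones((4, 1)))
        fit.coefficients = np.array([math.log(2)])
        fit.standard_errors = np.array([3.7])
        fit.term_names = ("x",)
        or_, lo, hi, _ = wald_or_ci(fit, "x")
        assert or_ == pytest.approx(2.0)
        assert lo <= or_ <= hi

    def test_missing_term_raises(self):
        fit = fit_bayes_logistic(np.array([0.0, 1.0]), np.ones((2, 1)))
        with pytest.raises(KeyError):
            wald_or_ci(fit, "nope")


# ---------------------------------------------------------------------------
# classical machinery
# ---------------------------------------------------------------------------


class TestBH:
    def test_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.3] * 7), [0.3] * 7)

    def test_sorted_q_nondecreasing(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestWilson:
    def test_zero_successes_lower_bound(self):
        lo, hi = wilson_interval(0, 10)
        assert lo == pytest.approx(0.0)

    def test_closed_form_half(self):
        lo, hi = wilson_interval(5, 10)
        assert lo == pytest.approx(0.2366, abs=1e-3)
        assert hi == pytest.approx(0.7634, abs=1e-3)

    @pytest.mark.parametrize("k,n", [(0, 1), (3, 7), (7, 7), (50, 200)])
    def test_contained_in_unit_interval(self, k, n):
        lo, hi = wilson_interval(k, n)
        assert 0.0 <= lo <= hi <= 1.0

    def test_n_zero_raises(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestFisher:
    def test_enumeration_example(self):
        p, orr = fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(0.4857, abs=1e-4)

    def test_symmetric_table(self):
        p, orr = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert orr == pytest.approx(1.0)

    def test_zero_cell_gives_finite_corrected_or(self):
        p, orr = fisher_exact_2x2(ContingencyTable2x2(4, 0, 2, 6))
        assert np.isfinite(orr) and orr > 0
        assert orr == pytest.approx((4.5 * 6.5) / (0.5 * 2.5))

    def test_all_zero_table(self):
        p, orr = fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 0))
        assert p == 1.0
        assert math.isnan(orr)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_two_sided_enum(a, b, c, d), abs=1e-10)

    def test_haldane_no_correction_when_positive(self):
        assert haldane_odds_ratio(2, 3, 4, 5) == pytest.approx((2 * 5) / (3 * 4))


class TestHypergeom:
    def test_exact_enumeration_example(self):
        assert hypergeom_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(30, 6, 9, 0) == pytest.approx(1.0)

    def test_forced_overlap(self):
        # set B is the whole universe: every element of A overlaps
        assert hypergeom_tail(12, 4, 12, 4) == pytest.approx(1.0)

    def test_pmf_sums_to_one(self):
        for N, m, n in [(20, 5, 8), (50, 20, 15), (7, 3, 3)]:
            total = sum(
                hypergeom_tail(N, m, n, k) - hypergeom_tail(N, m, n, k + 1)
                if k < min(m, n)
                else hypergeom_tail(N, m, n, k)
                for k in range(0, min(m, n) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 4, 5, 6)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 14, 5, 2)


class TestWelch:
    def test_identical_constant_groups(self):
        t, df, p = welch_t_test([2, 2, 2], [2, 2, 2])
        assert t == 0.0 and p == 1.0

    def test_clear_separation(self):
        _, _, p = welch_t_test([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_textbook_formula_on_fixed_sample(self):
        x = np.array([4.1, 5.2, 6.3, 4.8, 5.5])
        y = np.array([7.9, 8.1, 6.9, 7.2, 8.4])
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1) / 5, y.var(ddof=1) / 5
        t_ref = (mx - my) / math.sqrt(vx + vy)
        df_ref = (vx + vy) ** 2 / (vx**2 / 4 + vy**2 / 4)
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        t, df, p = welch_t_test(x, y)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


def test_penalized_loglik_is_finite_at_zero():
    y = np.array([0.0, 1.0, 1.0])
    X = np.column_stack([np.ones(3), [0.0, 1.0, 0.0]])
    val = penalized_loglik(y, X, np.zeros(2), PriorSpec())
    assert np.isfinite(val)


def test_format_p_floor():
    assert format_p(1e-300) == "< 2.2e-16"
    assert format_p(0.0123) == "0.0123"
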