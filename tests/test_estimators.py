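"""Wald ratio, IVW, weighted median, MR-Egger, and CI arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.estimators import (RatioEstimate, confidence_interval, egger, ivw,
                              wald_ratio, weighted_median)

from conftest import make_instrument


def ratio(b, se, rsid="rs"):
    return RatioEstimate(rsid=rsid, beta_ratio=b, se_ratio=se)


def random_instruments(rng, j=10):
    g = rng.uniform(0.02, 0.1, j) * rng.choice([-1, 1], j)
    sy = rng.uniform(0.005, 0.02, j)
    G = 0.2 * g + rng.normal(0, sy)
    return [make_instrument(rsid=f"rs{i}", gamma=g[i], sx=0.003, Gamma=G[i], sy=sy[i])
            for i in range(j)]


def wls_oracle(x, y, w, intercept=True):
    """Weighted least squares by the normal equations; independent of the
    statsmodels fitting path used in the implementation."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid = y - X @ beta
    rss_w = float(resid @ W @ resid)
    cov = np.linalg.inv(X.T @ W @ X) * max(1.0, rss_w / (len(x) - X.shape[1]))
    return beta, np.sqrt(np.diag(cov))


class TestWaldRatio:
    def test_closed_form(self):
        r = wald_ratio(make_instrument(gamma=0.1, Gamma=0.02, sy=0.01))
        assert r.beta_ratio == pytest.approx(0.2)
        assert r.se_ratio == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_instrument(Gamma=0.0)).beta_ratio == 0.0

    def test_negative_exposure_effect_uses_absolute_se(self):
        r = wald_ratio(make_instrument(gamma=-0.1, Gamma=0.02, sy=0.01))
        assert r.beta_ratio == pytest.approx(-0.2)
        assert r.se_ratio == pytest.approx(0.1)

    def test_zero_exposure_effect_fatal(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_instrument(gamma=0.0))


class TestIvw:
    def test_two_ratio_hand_example(self):
        # weights 100 and 25: beta = (100*0.2 + 25*0.4)/125 = 0.24
        res = ivw([ratio(0.2, 0.1), ratio(0.4, 0.2)], "fixed")
        assert res.beta == pytest.approx(0.24)
        assert res.se == pytest.approx(1 / np.sqrt(125))

    def test_single_ratio_degenerates_to_wald(self):
        res = ivw([ratio(0.2, 0.1)])
        assert res.beta == pytest.approx(0.2) and res.se == pytest.approx(0.1)
        assert "single instrument" in res.notes

    def test_identical_ratios_fixed_equals_random(self):
        rs = [ratio(0.3, 0.1, f"r{i}") for i in range(5)]
        f, r = ivw(rs, "fixed"), ivw(rs, "random")
        assert f.beta == r.beta == pytest.approx(0.3)
        assert f.se == r.se  # Q = 0 so the scale factor is capped at 1

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            ivw([])

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 0.5)),
                    min_size=2, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_fixed_random_share_point_estimate_random_se_geq(self, pairs):
        rs = [ratio(b, se, f"r{i}") for i, (b, se) in enumerate(pairs)]
        f, r = ivw(rs, "fixed"), ivw(rs, "random")
        assert f.beta == r.beta
        assert r.se >= f.se

    def test_equal_weights_equal_mean(self):
        rs = [ratio(b, 0.1, f"r{i}") for i, b in enumerate([0.1, 0.2, 0.6])]
        assert ivw(rs).beta == pytest.approx(np.mean([0.1, 0.2, 0.6]))

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(100):
            ins = random_instruments(rng, j=int(rng.integers(3, 15)))
            res = ivw([wald_ratio(i) for i in ins], "fixed")
            g = np.array([i.gamma_hat for i in ins])
            G = np.array([i.capital_gamma_hat for i in ins])
            w = np.array([i.sigma_y for i in ins]) ** -2.0
            beta, _ = wls_oracle(g, G, w, intercept=False)
            assert res.beta == pytest.approx(float(beta[0]), abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_is_middle_order_statistic(self):
        rs = [ratio(b, 1.0, f"r{i}") for i, b in enumerate([0.9, 0.1, 0.2])]
        assert weighted_median(rs, n_boot=100, seed=0).beta == pytest.approx(0.2)

    def test_dominant_weight_pulls_estimate(self):
        rs = [ratio(0.1, 1.0, "a"), ratio(0.2, 1.0, "b"), ratio(0.9, 1 / np.sqrt(98), "c")]
        est = weighted_median(rs, n_boot=100, seed=0).beta
        # brute-force cumulative-weight interpolation oracle
        b = np.array([0.1, 0.2, 0.9]); w = np.array([1.0, 1.0, 98.0])
        s = (np.cumsum(w) - w / 2) / w.sum()
        assert est == pytest.approx(float(np.interp(0.5, s, b)))
        assert est > 0.85

    def test_bootstrap_reproducible_under_seed(self):
        rs = [ratio(b, 0.1, f"r{i}") for i, b in enumerate([0.1, 0.25, 0.3, 0.5])]
        a = weighted_median(rs, n_boot=200, seed=7)
        b = weighted_median(rs, n_boot=200, seed=7)
        assert a.se == b.se and a.beta == b.beta

    def test_reordering_invariance_and_range(self, rng):
        base = [ratio(float(b), float(se), f"r{i}") for i, (b, se) in
                enumerate(zip(rng.normal(0.2, 0.3, 9), rng.uniform(0.05, 0.4, 9)))]
        est = weighted_median(base, n_boot=100, seed=1).beta
        perm = [base[i] for i in rng.permutation(9)]
        assert weighted_median(perm, n_boot=100, seed=1).beta == pytest.approx(est)
        betas = [r.beta_ratio for r in base]
        assert min(betas) <= est <= max(betas)

    def test_too_few_instruments_fatal(self):
        with pytest.raises(ValueError):
            weighted_median([ratio(0.1, 1), ratio(0.2, 1)], n_boot=100, seed=0)


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.02, 0.05, 0.08, 0.11])
        ins = [make_instrument(rsid=f"r{i}", gamma=g[i], Gamma=0.05 + 0.3 * g[i])
               for i in range(4)]
        slope, intercept = egger(ins)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.05, abs=1e-12)

    def test_slope_through_zero_intercept_equals_ivw(self):
        # points on a perfect line through the origin: Egger finds zero
        # intercept and its slope equals the IVW estimate
        g = np.array([0.02, 0.05, 0.08, 0.11])
        ins = [make_instrument(rsid=f"r{i}", gamma=g[i], Gamma=0.3 * g[i]) for i in range(4)]
        slope, intercept = egger(ins)
        res = ivw([wald_ratio(i) for i in ins])
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(res.beta, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            ins = random_instruments(rng, j=10)
            slope, intercept = egger(ins)
            g = np.array([i.gamma_hat for i in ins])
            G = np.array([i.capital_gamma_hat for i in ins])
            sign = np.where(g < 0, -1.0, 1.0)
            w = np.array([i.sigma_y for i in ins]) ** -2.0
            beta, se = wls_oracle(g * sign, G * sign, w)
            assert intercept.beta == pytest.approx(float(beta[0]), abs=1e-10)
            assert slope.beta == pytest.approx(float(beta[1]), abs=1e-10)
            assert intercept.se == pytest.approx(float(se[0]), abs=1e-10)
            assert slope.se == pytest.approx(float(se[1]), abs=1e-10)

    def test_sign_flip_equivariance(self, rng):
        ins = random_instruments(rng, j=8)
        flipped = [make_instrument(rsid=i.rsid, gamma=-i.gamma_hat, sx=i.sigma_x,
                                   Gamma=-i.capital_gamma_hat, sy=i.sigma_y)
                   for i in ins]
        s1, i1 = egger(ins)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)
        r1 = ivw([wald_ratio(i) for i in ins])
        r2 = ivw([wald_ratio(i) for i in flipped])
        assert r1.beta == pytest.approx(r2.beta)

    def test_degenerate_inputs_fatal(self):
        with pytest.raises(ValueError):
            egger([make_instrument(rsid="a"), make_instrument(rsid="b")])
        same = [make_instrument(rsid=f"r{i}", gamma=0.05) for i in range(4)]
        with pytest.raises(ValueError):
            egger(same)


class TestConfidenceInterval:
    def test_standard_normal_quantile(self):
        lo, hi = confidence_interval(0.0, 1.0)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    @pytest.mark.parametrize("beta,se,expected_low,expected_high", [
        (0.126, 0.017, 0.093, None),      # LA maximal volume, published bound
        (-0.105, 0.017, -0.138, -0.072),  # LA passive emptying fraction
    ])
    def test_reproduces_published_bounds_after_rounding(self, beta, se,
                                                        expected_low, expected_high):
        lo, hi = confidence_interval(beta, se)
        assert round(lo, 3) == expected_low
        if expected_high is not None:
            assert round(hi, 3) == expected_high

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            confidence_interval(0, 0)
        with pytest.raises(ValueError):
            confidence_interval(0, 1, level=1.0)
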