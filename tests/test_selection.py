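import numpy as np
import pytest

from conftest import make_posterior
from phenomatch.selection import (covariance_summary, optimum_sensitivity,
                                  slope_variance, summarize, vertex)
from phenomatch.trends import TrendFit


def trend(slope, se=0.0):
    return TrendFit(slope=slope, slope_se=se, intercept=0.0, p_value=1.0,
                    phi=0.0, n=30)


class TestSummarize:
    def test_constant_draws(self):
        post = make_posterior({"a": np.full(200, 3.0),
                               "b": np.zeros(200)})
        s = summarize(post).set_index("parameter")
        assert s.loc["a", "mean"] == 3.0
        assert (s.loc["a", "ci_low"], s.loc["a", "ci_high"]) == (3.0, 3.0)
        assert bool(s.loc["a", "significant"])
        assert not bool(s.loc["b", "significant"])

    def test_sign_alternating_draws_not_significant(self):
        post = make_posterior({"a": np.tile([-1.0, 1.0], 100)})
        s = summarize(post).set_index("parameter")
        assert not bool(s.loc["a", "significant"])

    def test_normal_quantile_oracle(self):
        rng = np.random.default_rng(0)
        post = make_posterior({"a": rng.standard_normal(10_000)})
        s = summarize(post).set_index("parameter")
        assert s.loc["a", "ci_low"] == pytest.approx(-1.96, abs=0.08)
        assert s.loc["a", "ci_high"] == pytest.approx(1.96, abs=0.08)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            summarize(make_posterior({"a": np.zeros(10)}))


class TestVertex:
    def test_constant_ratio(self):
        post = make_posterior({"rel_laydate": np.full(500, -0.026),
                               "rel_laydate_sq": np.full(500, -0.0007)})
        v = vertex(post)
        assert v.mean == pytest.approx(-0.026 / (2 * 0.0007), abs=1e-9)
        assert v.mean == pytest.approx(-18.5714285714, abs=1e-9)

    def test_zero_linear_term(self):
        post = make_posterior({"rel_laydate": np.zeros(500),
                               "rel_laydate_sq": np.full(500, -0.0007)})
        assert vertex(post).mean == 0.0

    def test_zero_quadratic_draws_excluded_with_warning(self):
        a = np.full(500, -0.0007)
        a[:100] = 0.0
        post = make_posterior({"rel_laydate": np.full(500, -0.026),
                               "rel_laydate_sq": a})
        with pytest.warns(UserWarning, match="zero quadratic"):
            v = vertex(post)
        assert v.n_excluded == 100


class TestOptimumSensitivity:
    def test_reduces_to_timing_trend_exactly(self):
        post = make_posterior({"rel_laydate": np.full(500, -0.026),
                               "rel_laydate_sq": np.full(500, -0.0007),
                               "rel_x_year": np.zeros(500)})
        sens = optimum_sensitivity(post, trend(-0.94), covariate="year")
        assert sens.mean == -0.94
        assert sens.relative_optimum_component == 0.0

    def test_zero_everything_gives_zero(self):
        post = make_posterior({"rel_laydate": np.zeros(500),
                               "rel_laydate_sq": np.full(500, -0.0007),
                               "rel_x_year": np.zeros(500)})
        assert optimum_sensitivity(post, trend(0.0), "year").mean == 0.0

    def test_missing_interaction_names_variant(self):
        post = make_posterior({"rel_laydate": np.zeros(500),
                               "rel_laydate_sq": np.full(500, -0.0007)})
        with pytest.raises(ValueError, match="year"):
            optimum_sensitivity(post, trend(0.0), "year")

    def test_interaction_shifts_optimum(self):
        # B = dxbar/dE - b_int/(2a): with b_int=-0.0014, a=-0.0007, B=t-1
        post = make_posterior({"rel_laydate": np.zeros(500),
                               "rel_laydate_sq": np.full(500, -0.0007),
                               "rel_x_year": np.full(500, -0.0014)})
        sens = optimum_sensitivity(post, trend(-0.5), "year")
        assert sens.mean == pytest.approx(-1.5, abs=1e-12)


class TestCovarianceSummary:
    def test_identity_draws(self):
        post = make_posterior(
            {"a": np.zeros(200)},
            cov=np.broadcast_to(np.eye(4), (200, 4, 4)).copy(),
            re_names=["B_Sh", "B_Sa", "W_Sh", "W_Sa"])
        t = covariance_summary(post).set_index("entry")
        assert t.loc["cov(B_Sh,B_Sa)", "mean"] == 0.0
        assert t.loc["cov(B_Sh,B_Sa)", "correlation"] == 0.0
        assert t.loc["var(B_Sh)", "mean"] == 1.0

    def test_constant_covariance_reported(self):
        c = np.eye(4)
        c[2, 3] = c[3, 2] = 0.0003
        c[2, 2] = c[3, 3] = 0.01
        post = make_posterior(
            {"a": np.zeros(200)},
            cov=np.broadcast_to(c, (200, 4, 4)).copy(),
            re_names=["B_Sh", "B_Sa", "W_Sh", "W_Sa"])
        t = covariance_summary(post).set_index("entry")
        assert t.loc["cov(W_Sh,W_Sa)", "mean"] == pytest.approx(0.0003)

    def test_correlations_bounded_on_random_psd_draws(self):
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(300):
            A = rng.standard_normal((4, 6))
            draws.append(A @ A.T / 6)
        post = make_posterior({"a": np.zeros(300)},
                              cov=np.stack(draws),
                              re_names=["B_Sh", "B_Sa", "W_Sh", "W_Sa"])
        t = covariance_summary(post)
        off = t[t["trait_a"] != t["trait_b"]]
        assert (off["correlation"].abs() <= 1.0 + 1e-12).all()


class TestSlopeVariance:
    def test_quantile_summary(self):
        rng = np.random.default_rng(1)
        d = rng.chisquare(3, size=2000) * 1e-4
        cov = np.zeros((2000, 2, 2))
        cov[:, 1, 1] = d
        post = make_posterior({"a": np.zeros(2000)}, cov=cov)
        sv = slope_variance(post)
        assert sv.mean == pytest.approx(d.mean())
        assert sv.ci_low == pytest.approx(np.quantile(d, 0.025))
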