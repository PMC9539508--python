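"""The REML/ML fitter against closed forms, statsmodels, and its own identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from revegrowth.design import ModelSpec
from revegrowth.lmm import (
    FitResult,
    MixedModelMatrices,
    aic,
    fit_lmm,
    lrt,
    make_matrices,
    pseudo_r2,
)


def balanced_one_way(seed, k=40, m=10, sigma_g=1.0, sigma_e=1.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(k), m)
    y = 2.0 + rng.normal(0, sigma_g, k)[groups] + rng.normal(0, sigma_e, k * m)
    return y, groups


def anova_varcomps(y, k, m):
    """Method-of-moments closed form for the balanced one-way layout."""
    cell = y.reshape(k, m)
    gbar = cell.mean(axis=1)
    msb = m * np.sum((gbar - y.mean()) ** 2) / (k - 1)
    msw = np.sum((cell - gbar[:, None]) ** 2) / (k * (m - 1))
    return (msb - msw) / m, msw


class TestFitLmm:
    def test_noiseless_limit_recovers_beta_exactly(self, rng):
        n = 300
        x = pd.DataFrame(
            {"intercept": np.ones(n), "a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        beta = np.array([0.5, -0.2, 0.1])
        y = x.to_numpy() @ beta  # no random effects, no residual noise
        fit = MixedModelMatrices(x, {"g": rng.integers(0, 10, n)}).fit(y)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)
        assert all(v < 1e-8 for v in fit.varcomps.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_reml_equals_anova_closed_form(self, seed):
        y, groups = balanced_one_way(seed)
        fit = MixedModelMatrices(
            pd.DataFrame({"intercept": np.ones(len(y))}), {"group": groups}
        ).fit(y, method="REML")
        s2g, s2e = anova_varcomps(y, 40, 10)
        assert fit.varcomps["group"] == pytest.approx(s2g, abs=1e-6)
        assert fit.varcomps["resid"] == pytest.approx(s2e, abs=1e-6)

    def test_reml_and_ml_fixed_effects_agree_on_balanced_design(self):
        y, groups = balanced_one_way(3)
        mats = MixedModelMatrices(
            pd.DataFrame({"intercept": np.ones(len(y))}), {"group": groups}
        )
        reml = mats.fit(y, method="REML")
        ml = mats.fit(y, method="ML")
        np.testing.assert_allclose(
            reml.beta.to_numpy(), ml.beta.to_numpy(), atol=1e-6
        )

    def test_crossed_factors_match_statsmodels(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        n = 400
        f1 = rng.integers(0, 12, n)
        f2 = rng.integers(0, 9, n)
        x = rng.normal(size=n)
        y = (
            1.0
            + 0.5 * x
            + rng.normal(0, 0.7, 12)[f1]
            + rng.normal(0, 0.5, 9)[f2]
            + rng.normal(0, 1.0, n)
        )
        df = pd.DataFrame({"y": y, "x": x, "f1": f1, "f2": f2, "g": 1})
        sm_fit = smf.mixedlm(
            "y ~ x", df, groups="g", vc_formula={"f1": "0 + C(f1)", "f2": "0 + C(f2)"}
        ).fit(reml=True)
        ours = MixedModelMatrices(
            pd.DataFrame({"intercept": np.ones(n), "x": x}), {"f1": f1, "f2": f2}
        ).fit(y, method="REML")
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        np.testing.assert_allclose(
            ours.beta.to_numpy(), sm_fit.fe_params.values, atol=1e-5
        )
        np.testing.assert_allclose(
            [ours.varcomps["f1"], ours.varcomps["f2"], ours.varcomps["resid"]],
            [sm_fit.vcomp[0], sm_fit.vcomp[1], sm_fit.scale],
            atol=1e-4,
        )

    def test_row_permutation_invariance(self, small_frame):
        from revegrowth.design import build_model_ladder

        spec = build_model_ladder(predictors=("age", "density"))["genus_slopes"]
        data = small_frame.data
        fit1 = fit_lmm(data["rgr"], spec, data)
        shuffled = data.sample(frac=1.0, random_state=99)
        fit2 = fit_lmm(shuffled["rgr"], spec, shuffled)
        np.testing.assert_allclose(
            fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            fit1.varcomps.to_numpy(), fit2.varcomps.to_numpy(), atol=1e-10
        )

    def test_single_level_factor_dropped_with_warning(self, rng):
        n = 100
        x = pd.DataFrame({"intercept": np.ones(n)})
        with pytest.warns(UserWarning, match="dropped"):
            mats = MixedModelMatrices(x, {"g": np.zeros(n), "h": rng.integers(0, 5, n)})
        assert mats.factor_names == ["h"]

    def test_rank_deficient_design_rejected(self, rng):
        n = 50
        a = rng.normal(size=n)
        x = pd.DataFrame({"intercept": np.ones(n), "a": a, "b": 2 * a})
        with pytest.raises(np.linalg.LinAlgError):
            MixedModelMatrices(x, {"g": rng.integers(0, 5, n)})


class TestAic:
    def _fake_fit(self, method="ML", loglik=-100.0, n_params=5):
        idx = ["intercept"]
        return FitResult(
            spec=None,
            method=method,
            beta=pd.Series([0.0], index=idx),
            beta_cov=pd.DataFrame([[1.0]], index=idx, columns=idx),
            varcomps=pd.Series({"resid": 1.0}),
            loglik=loglik,
            n_obs=10,
            n_params=n_params,
            converged=True,
        )

    def test_formula(self):
        assert aic(self._fake_fit()) == pytest.approx(210.0)

    def test_reml_fit_rejected(self):
        with pytest.raises(ValueError, match="ML"):
            aic(self._fake_fit(method="REML"))

    def test_recomputation_matches_stored_loglik(self, small_frame):
        from revegrowth.design import build_model_ladder

        spec = build_model_ladder(predictors=("age",))["no_genus"]
        fit = fit_lmm(small_frame.y, spec, small_frame.data, method="ML")
        assert aic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-10)


@pytest.fixture(scope="module")
def two_fits(small_frame):
    from revegrowth.design import build_model_ladder

    ladder = build_model_ladder(predictors=("age", "density"))
    small = fit_lmm(small_frame.y, ladder["no_genus"], small_frame.data, method="ML")
    big = fit_lmm(small_frame.y, ladder["genus_slopes"], small_frame.data, method="ML")
    return small, big


class TestLrt:
    def test_self_comparison_is_null(self, two_fits):
        small, _ = two_fits
        out = lrt(small, small)
        assert out.chi2 == 0.0
        assert out.p_value == 1.0

    def test_chi2_nonnegative_for_nested_pair(self, two_fits):
        small, big = two_fits
        out = lrt(small, big)
        assert out.chi2 >= 0.0
        assert out.df == big.n_params - small.n_params
        assert 0.0 <= out.p_value <= 1.0

    def test_non_nested_rejected(self, small_frame):
        from revegrowth.design import build_model_ladder

        ladder = build_model_ladder(predictors=("age", "density"))
        bigger = fit_lmm(small_frame.y, ladder["genus_slopes"], small_frame.data, method="ML")
        smaller = fit_lmm(small_frame.y, ladder["no_genus"], small_frame.data, method="ML")
        with pytest.raises(ValueError, match="not nested"):
            lrt(bigger, smaller)  # arguments reversed: genus_slopes is not inside no_genus

    def test_reml_fits_rejected(self, small_frame):
        from revegrowth.design import build_model_ladder

        ladder = build_model_ladder(predictors=("age",))
        f = fit_lmm(small_frame.y, ladder["no_genus"], small_frame.data, method="REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(f, f)

    def test_null_chi2_distribution(self):
        """Under truly-zero extra terms the LRT statistic follows chi-square."""
        rng = np.random.default_rng(11)
        n, k, df_extra = 150, 15, 3
        groups = np.tile(np.arange(k), n // k)
        chi2s = []
        for _ in range(150):
            extra = rng.normal(size=(n, df_extra))
            y = 1.0 + rng.normal(0, 0.5, k)[groups] + rng.normal(0, 1.0, n)
            x_small = pd.DataFrame({"intercept": np.ones(n)})
            x_big = pd.concat(
                [x_small, pd.DataFrame(extra, columns=list("abc"))], axis=1
            )
            f_small = MixedModelMatrices(x_small, {"g": groups}).fit(y, method="ML")
            f_big = MixedModelMatrices(x_big, {"g": groups}).fit(y, method="ML")
            chi2s.append(max(0.0, 2.0 * (f_big.loglik - f_small.loglik)))
        ks = stats.kstest(chi2s, stats.chi2(df_extra).cdf)
        assert ks.pvalue > 0.01


class TestPseudoR2:
    def test_conditional_at_least_marginal(self, small_frame):
        from revegrowth.design import build_model_ladder

        spec = build_model_ladder(predictors=("age", "density"))["genus_slopes"]
        fit = fit_lmm(small_frame.y, spec, small_frame.data)
        marg, cond = pseudo_r2(fit)
        assert 0.0 <= marg <= cond <= 1.0

    def test_intercept_only_marginal_is_zero(self, small_frame):
        spec = ModelSpec("base", ("intercept",))
        fit = fit_lmm(small_frame.y, spec, small_frame.data)
        marg, cond = pseudo_r2(fit)
        assert marg == pytest.approx(0.0, abs=1e-12)
        var_r = sum(v for k, v in fit.varcomps.items() if k != "resid")
        assert cond == pytest.approx(var_r / (var_r + fit.varcomps["resid"]), abs=1e-12)

    def test_no_random_variance_collapses_to_marginal(self, rng):
        n = 500
        x = pd.DataFrame({"intercept": np.ones(n), "a": rng.normal(size=n)})
        y = x.to_numpy() @ np.array([1.0, 0.5]) + rng.normal(0, 1.0, n)
        fit = MixedModelMatrices(x, {}).fit(y)
        marg, cond = pseudo_r2(fit)
        assert marg == pytest.approx(cond)

    def test_variance_share_recovered(self, rng):
        n, k = 5000, 50
        groups = np.tile(np.arange(k), n // k)
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(0, 0.6, k)[groups] + rng.normal(0, 0.8, n)
        fit = MixedModelMatrices(
            pd.DataFrame({"intercept": np.ones(n), "x": x}), {"g": groups}
        ).fit(y)
        marg, _ = pseudo_r2(fit)
        truth = 0.64 / (0.64 + 0.36 + 0.64)
        assert marg == pytest.approx(truth, abs=0.05)
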