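"""Mixed-effects engine: oracles, invariances, recovery, model comparison."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from tmsdecay import (
    CohortConfig,
    DecayParams,
    ExponentialDecayModel,
    LinearResponseModel,
    RatingSeries,
    ScaleSpec,
    compare_models,
    generate_cohort,
    marginal_loglik,
    select_random_effects,
)
from tmsdecay.series import cohort_to_frame

WIDE = ScaleSpec("WIDE", -100.0, 200.0, remission_cutoff=5)
WIDER = ScaleSpec("WIDER", -400.0, 600.0, remission_cutoff=5)


def _fit(cohort, re="AC", **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ExponentialDecayModel(cohort).fit(random_effects=re, **kw)


def _fit_lme(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LinearResponseModel(cohort).fit()


class TestNLMEOracles:
    def test_noiseless_cohort_recovers_generating_values(self, noiseless_cohort, true_params):
        res = _fit(noiseless_cohort)
        assert res.fixed.amplitude == pytest.approx(true_params.amplitude, abs=1e-4)
        assert res.fixed.time_constant == pytest.approx(true_params.time_constant, abs=1e-4)
        assert res.fixed.floor == pytest.approx(true_params.floor, abs=1e-4)
        assert np.all(np.diag(res.re_covariance.to_numpy()) < 1e-6)

    def test_marginal_likelihood_matches_dense_quadrature_linear_effect(self, toy_cohort):
        """Random effect on the floor: quadrature oracle, exact agreement."""
        p = DecayParams(9.0, 1.3, 10.0)
        psi, sig = 4.0, 1.5

        def quad_ll(s):
            def integrand(c):
                mu = p.a * np.exp(-s.times / p.b) + p.c + c
                return float(
                    np.prod(stats.norm.pdf(s.scores, mu, sig))
                    * stats.norm.pdf(c, 0, np.sqrt(psi))
                )

            val, _ = integrate.quad(
                integrand, -12 * np.sqrt(psi), 12 * np.sqrt(psi), limit=200
            )
            return np.log(val)

        oracle = sum(quad_ll(s) for s in toy_cohort)
        mine = marginal_loglik(toy_cohort, p, [[psi]], sig, "C")
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_laplace_approximation_close_to_quadrature_nonlinear_effect(self, toy_cohort):
        """Random effect on log B: Laplace is approximate; quantify the gap."""
        p = DecayParams(9.0, 1.3, 10.0)
        psi, sig = 0.04, 1.5

        def quad_ll(s):
            def integrand(u):
                mu = p.a * np.exp(-s.times / (p.b * np.exp(u))) + p.c
                return float(
                    np.prod(stats.norm.pdf(s.scores, mu, sig))
                    * stats.norm.pdf(u, 0, np.sqrt(psi))
                )

            val, _ = integrate.quad(
                integrand, -12 * np.sqrt(psi), 12 * np.sqrt(psi), limit=200
            )
            return np.log(val)

        oracle = sum(quad_ll(s) for s in toy_cohort)
        mine = marginal_loglik(toy_cohort, p, [[psi]], sig, "B")
        assert mine == pytest.approx(oracle, abs=0.1)

    def test_zero_variance_limit_equals_independent_gaussian_loglik(self, toy_cohort):
        """With no between-subject variance the model degrades to iid errors."""
        p = DecayParams(9.0, 1.3, 10.0)
        sig = 1.5
        direct = sum(
            float(
                np.sum(
                    stats.norm.logpdf(
                        s.scores, p.a * np.exp(-s.times / p.b) + p.c, sig
                    )
                )
            )
            for s in toy_cohort
        )
        mine = marginal_loglik(toy_cohort, p, [[1e-300]], sig, "C")
        assert mine == pytest.approx(direct, abs=1e-6)


class TestNLMEInvariances:
    def test_repeated_fits_are_identical(self, default_cohort):
        r1 = _fit(default_cohort)
        r2 = _fit(default_cohort)
        assert r1.fixed == r2.fixed
        assert r1.llf == r2.llf

    def test_likelihood_invariant_to_subject_relabeling(self, default_cohort):
        r1 = _fit(default_cohort)
        shuffled = [default_cohort[i] for i in
                    np.random.default_rng(0).permutation(len(default_cohort))]
        r2 = _fit(shuffled)
        assert r2.llf == pytest.approx(r1.llf, abs=1e-6)
        assert r2.fixed.time_constant == pytest.approx(r1.fixed.time_constant, abs=1e-6)

    def test_affine_equivariance_of_fixed_effects(self):
        cohort = generate_cohort(
            CohortConfig(seed=9, n_subjects=40, scale=WIDE, discretize=False)
        )
        rescaled = [
            RatingSeries(s.subject_id, s.times, 2.0 * s.scores + 1.0, WIDER)
            for s in cohort
        ]
        r1, r2 = _fit(cohort), _fit(rescaled)
        assert r2.fixed.amplitude == pytest.approx(2 * r1.fixed.amplitude, rel=1e-3)
        assert r2.fixed.floor == pytest.approx(2 * r1.fixed.floor + 1, rel=1e-3)
        assert r2.fixed.time_constant == pytest.approx(r1.fixed.time_constant, rel=1e-3)

    def test_aic_bic_identities(self, default_cohort):
        res = _fit(default_cohort)
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params, abs=1e-10)
        assert res.bic == pytest.approx(
            -2 * res.llf + res.n_params * np.log(res.n_obs), abs=1e-10
        )

    def test_wald_tests_significant_on_default_cohort(self, default_cohort):
        res = _fit(default_cohort)
        assert all(p < 0.05 for p in res.pvalues.values())


class TestLME:
    def test_exactly_linear_cohort_recovered_at_zero_noise_boundary(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        cohort = [
            RatingSeries(f"s{i}", t, 15.0 - 1.5 * t, WIDE) for i in range(4)
        ]
        res = _fit_lme(cohort)
        assert res.intercept == pytest.approx(15.0, abs=1e-4)
        assert res.slope == pytest.approx(-1.5, abs=1e-4)
        assert res.residual_sd < 1e-4

    def test_loglik_matches_closed_form_gaussian_density(self):
        rng = np.random.default_rng(3)
        cohort = []
        for i in range(30):
            t = np.arange(7.0)
            u, v = rng.multivariate_normal([15, -1.2], [[9, -0.5], [-0.5, 0.25]])
            cohort.append(
                RatingSeries(f"s{i}", t, u + v * t + 0.8 * rng.standard_normal(7), WIDE)
            )
        res = _fit_lme(cohort)
        psi = res.re_covariance.to_numpy()
        direct = 0.0
        for s in cohort:
            Z = np.column_stack([np.ones_like(s.times), s.times])
            V = Z @ psi @ Z.T + res.residual_sd**2 * np.eye(len(s))
            mu = res.intercept + res.slope * s.times
            direct += stats.multivariate_normal.logpdf(s.scores, mu, V)
        assert res.llf == pytest.approx(direct, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        rng = np.random.default_rng(3)
        cohort = []
        for i in range(40):
            t = np.arange(7.0)
            u, v = rng.multivariate_normal([15, -1.2], [[9, -0.5], [-0.5, 0.25]])
            cohort.append(
                RatingSeries(f"s{i}", t, u + v * t + 0.8 * rng.standard_normal(7), WIDE)
            )
        res = _fit_lme(cohort)
        df = cohort_to_frame(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smres = sm.MixedLM.from_formula(
                "score ~ time", df, groups=df["subject_id"], re_formula="~time"
            ).fit(reml=False)
        assert res.llf == pytest.approx(smres.llf, abs=1e-4)
        assert res.intercept == pytest.approx(smres.params.iloc[0], abs=1e-3)
        assert res.slope == pytest.approx(smres.params.iloc[1], abs=1e-3)

    def test_parameter_recovery_from_linear_mixed_data(self):
        ints, slopes = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cohort = []
            for i in range(50):
                t = np.arange(7.0)
                u, v = rng.multivariate_normal([15, -1.2], [[9, -0.5], [-0.5, 0.25]])
                cohort.append(
                    RatingSeries(
                        f"s{i}", t, u + v * t + 0.8 * rng.standard_normal(7), WIDE
                    )
                )
            res = _fit_lme(cohort)
            ints.append(res.intercept)
            slopes.append(res.slope)
        for est, truth in ((np.array(ints), 15.0), (np.array(slopes), -1.2)):
            se = est.std(ddof=1) / np.sqrt(est.size)
            assert abs(est.mean() - truth) < 3 * se


class TestModelComparison:
    def test_fit_compared_with_itself_is_null(self, default_cohort):
        res = _fit(default_cohort)
        comp = compare_models(res, res)
        assert comp.lrt_stat == 0.0
        assert comp.delta_aic == 0.0

    def test_hand_computed_comparison(self):
        class Stub:
            def __init__(self, llf, k, n, name):
                self.llf, self.n_params, self.n_obs, self.name = llf, k, n, name
                self.aic = -2 * llf + 2 * k
                self.bic = -2 * llf + k * np.log(n)
                self.obs_fingerprint = "x"

        full, reduced = Stub(-100.0, 8, 200, "full"), Stub(-110.0, 6, 200, "reduced")
        comp = compare_models(full, reduced)
        assert comp.lrt_stat == pytest.approx(20.0)
        assert comp.df == 2
        assert comp.delta_aic == pytest.approx(-16.0)
        assert comp.p_value == pytest.approx(stats.chi2.sf(20.0, 2))

    def test_mismatched_observation_sets_rejected(self, default_cohort):
        r1 = _fit(default_cohort)
        other = generate_cohort(CohortConfig(seed=9999))
        r2 = _fit(other)
        with pytest.raises(ValueError, match="identical observation set"):
            compare_models(r1, r2)

    def test_nlme_beats_lme_on_decay_generated_cohorts(self):
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(seed=seed))
            nl, li = _fit(cohort), _fit_lme(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = compare_models(nl, li)
            wins += comp.delta_aic < 0 and comp.delta_bic < 0
        assert wins == n_seeds

    def test_nonnested_comparison_warns(self, default_cohort):
        nl, li = _fit(default_cohort), _fit_lme(default_cohort)
        with pytest.warns(UserWarning, match="non-nested"):
            compare_models(nl, li)


class TestRandomEffectsSelection:
    def test_without_time_constant_heterogeneity_simpler_model_chosen(self):
        cohort = generate_cohort(CohortConfig(seed=2, n_subjects=60))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec, comp, fit = select_random_effects(cohort)
        assert spec.which == ("A", "C")
        assert comp is not None

    def test_strong_time_constant_heterogeneity_detected(self):
        """With real B heterogeneity the LRT flags the richer model and the
        selection rule's conjunction (LRT and AIC and BIC) is applied
        consistently to whatever the criteria say."""
        cohort = generate_cohort(
            CohortConfig(seed=4, n_subjects=400, sd_log_time_constant=0.5)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec, comp, fit = select_random_effects(cohort)
        assert comp.p_value < 0.05
        assert comp.delta_aic < 0
        expect_rich = comp.p_value < 0.05 and comp.delta_aic < 0 and comp.delta_bic < 0
        assert spec.which == (("A", "B", "C") if expect_rich else ("A", "C"))
        # the richer fit must actually have picked up time-constant variance
        rich = fit if expect_rich else None
        if rich is not None:
            assert rich.re_covariance.loc["log(B)", "log(B)"] > 0.01

    def test_recovery_study_mean_estimates_without_censoring(self):
        """Unbiased recovery when scores are not censored at scale bounds."""
        A, B = [], []
        for seed in range(40):
            cohort = generate_cohort(
                CohortConfig(seed=seed, scale=WIDE, discretize=False)
            )
            res = _fit(cohort)
            A.append(res.fixed.amplitude)
            B.append(res.fixed.time_constant)
        for est, truth in ((np.array(A), 5.8), (np.array(B), 1.2)):
            se = est.std(ddof=1) / np.sqrt(est.size)
            assert abs(est.mean() - truth) < 3 * se
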