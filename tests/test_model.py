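"""Ordered-probit model mathematics: predictor, probabilities, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.special import ndtr

import rhibayes as rb


def make_params(n=3, k=7, **kw):
    defaults = dict(
        beta1=0.5,
        beta2=0.26,
        beta3=0.33,
        sigma_r=1.0,
        r=np.zeros(n),
        cutpoints=np.linspace(-2.5, 2.5, k - 1),
    )
    defaults.update(kw)
    return rb.ModelParameters(**defaults)


class TestLinearPredictor:
    def test_condition_zero_leaves_only_cia_main_effect(self):
        params = make_params(beta2=1.0, r=np.array([3.0, -1.0, 0.2]))
        assert rb.linear_predictor(params, cia=0.4, cond=0, i=0) == pytest.approx(0.4)

    def test_random_slope_adds_to_condition_effect(self):
        params = make_params(beta1=1.0, beta2=0.0, beta3=0.0, r=np.array([0.5, 0, 0]))
        assert rb.linear_predictor(params, cia=0.7, cond=1, i=0) == pytest.approx(1.5)

    def test_term_by_term_arithmetic(self):
        params = make_params(beta1=0.5, beta2=0.26, beta3=0.33, r=np.array([-0.2, 0, 0]))
        eta = rb.linear_predictor(params, cia=0.7, cond=1, i=0)
        assert eta == pytest.approx(0.3 + 0.182 + 0.231)

    def test_out_of_range_participant_index(self):
        with pytest.raises(IndexError):
            rb.linear_predictor(make_params(n=3), cia=0.5, cond=1, i=3)


class TestCategoryProbs:
    def test_symmetric_cutpoints_at_zero_eta(self):
        probs = rb.category_probs(0.0, (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5))
        assert probs.shape == (7,)
        assert probs[3] == pytest.approx(ndtr(0.5) - ndtr(-0.5), abs=1e-12)
        assert probs == pytest.approx(probs[::-1])

    def test_extreme_eta_saturates_top_category(self):
        probs = rb.category_probs(20.0, (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5))
        assert probs[-1] == pytest.approx(1.0, abs=1e-12)

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rb.category_probs(0.0, (0.5, 0.5, 1.0))

    @settings(deadline=None)
    @given(
        eta=st.floats(-8, 8),
        start=st.floats(-4, 1),
        steps=st.lists(st.floats(0.05, 2.0), min_size=2, max_size=10),
    )
    def test_probabilities_form_a_simplex(self, eta, start, steps):
        cuts = start + np.cumsum(steps)
        probs = rb.category_probs(eta, cuts)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None)
    @given(eta=st.floats(-3, 3), shift=st.floats(-5, 5))
    def test_shift_invariance(self, eta, shift):
        """Translating eta and all cutpoints together changes nothing:
        location identification lives entirely in the cutpoints."""
        cuts = np.array([-1.2, -0.3, 0.4, 1.7])
        base = rb.category_probs(eta, cuts)
        shifted = rb.category_probs(eta + shift, cuts + shift)
        assert shifted == pytest.approx(base, abs=1e-12)

    @settings(deadline=None)
    @given(eta=st.floats(-3, 3))
    def test_reflection_reverses_probabilities(self, eta):
        cuts = np.array([-1.2, -0.3, 0.4, 1.7])
        base = rb.category_probs(eta, cuts)
        reflected = rb.category_probs(-eta, -cuts[::-1])
        assert reflected == pytest.approx(base[::-1], abs=1e-12)


class TestLogLikelihood:
    def test_equals_sum_of_observation_log_probs(self, small_dataset):
        params = make_params(n=3, r=np.array([0.3, -0.4, 0.1]))
        expected = 0.0
        for i in range(3):
            for cond, y in ((0, small_dataset.y_async[i]), (1, small_dataset.y_sync[i])):
                eta = rb.linear_predictor(params, small_dataset.cia[i], cond, i)
                expected += math.log(rb.category_probs(eta, params.cutpoints)[y - 1])
        assert rb.log_likelihood(params, small_dataset) == pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_oracle(self, small_dataset):
        """Category probabilities agree with direct numerical integration of
        the standard-normal latent residual density over (tau_{k-1}-eta,
        tau_k-eta] at random parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            params = make_params(
                n=3,
                beta1=rng.normal(scale=1.5),
                beta2=rng.normal(scale=1.5),
                beta3=rng.normal(scale=1.5),
                sigma_r=float(rng.uniform(0.3, 2.0)),
                r=rng.normal(scale=1.0, size=3),
                cutpoints=np.sort(rng.normal(scale=2.0, size=6)),
            )
            expected = 0.0
            for i in range(3):
                for cond, y in (
                    (0, small_dataset.y_async[i]),
                    (1, small_dataset.y_sync[i]),
                ):
                    eta = rb.linear_predictor(params, small_dataset.cia[i], cond, i)
                    tau = np.concatenate(([-np.inf], params.cutpoints, [np.inf]))
                    p, _ = quad(
                        stats.norm.pdf, tau[y - 1] - eta, tau[y] - eta,
                        epsabs=1e-15, epsrel=1e-13, limit=200,
                    )
                    expected += math.log(max(p, 1e-300))
            assert rb.log_likelihood(params, small_dataset) == pytest.approx(
                expected, abs=1e-8
            )

    def test_swapping_to_lower_probability_category_lowers_loglik(self, small_dataset):
        params = make_params(n=3)
        base = rb.log_likelihood(params, small_dataset)
        worse = rb.AnalysisDataset(
            participants=small_dataset.participants,
            cia=small_dataset.cia,
            y_async=small_dataset.y_async,
            y_sync=np.array([1, 1, 1]),  # far from the predicted sync mean
            n_categories=7,
        )
        assert rb.log_likelihood(params, worse) < base

    def test_dimension_mismatch_is_error(self, small_dataset):
        with pytest.raises(ValueError, match="participants"):
            rb.log_likelihood(make_params(n=5), small_dataset)
        with pytest.raises(ValueError, match="K="):
            rb.log_likelihood(make_params(n=3, k=5), small_dataset)


class TestPriors:
    def test_prior_spec_families_match_scipy(self):
        """Closed-form log densities agree with the scipy reference."""
        x = np.array([0.1, 0.9, 2.5, 7.0])
        pairs = [
            (rb.PriorSpec("normal", 0.3, 1.7), stats.norm(0.3, 1.7)),
            (rb.PriorSpec("student_t", 0.0, 2.5, df=3), stats.t(3, 0.0, 2.5)),
            (rb.PriorSpec("half_normal", 0.0, 2.5), stats.halfnorm(0.0, 2.5)),
            (rb.PriorSpec("half_cauchy", 0.0, 2.5), stats.halfcauchy(0.0, 2.5)),
            (rb.PriorSpec("exponential", 0.0, 2.5), stats.expon(0.0, 2.5)),
        ]
        for spec, ref in pairs:
            assert spec.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-12)

    def test_half_cauchy_closed_form_at_scale(self):
        spec = rb.PriorSpec("half_cauchy", 0.0, 2.5)
        expected = math.log(2.0 / (math.pi * 2.5)) - math.log(2.0)
        assert float(spec.logpdf(2.5)) == pytest.approx(expected, rel=1e-12)

    def test_coefficient_contribution_at_zero(self):
        """With all betas zero the coefficient block contributes exactly
        three normal(0, 2.5) log densities at 0."""
        params = make_params(beta1=0, beta2=0, beta3=0, sigma_r=1.3)
        baseline = rb.log_prior(params)
        shifted = rb.log_prior(make_params(beta1=1.0, beta2=0, beta3=0, sigma_r=1.3))
        coef = stats.norm(0, 2.5)
        assert baseline - shifted == pytest.approx(
            coef.logpdf(0.0) - coef.logpdf(1.0), rel=1e-10
        )

    def test_each_extra_slope_adds_one_normal_term(self):
        small = make_params(n=2, r=np.zeros(2), sigma_r=1.4)
        large = make_params(n=5, r=np.zeros(5), sigma_r=1.4)
        per_term = stats.norm(0, 1.4).logpdf(0.0)
        assert rb.log_prior(large) - rb.log_prior(small) == pytest.approx(
            3 * per_term, rel=1e-10
        )

    def test_nonpositive_sigma_is_domain_error(self):
        with pytest.raises(ValueError, match="sigma_r"):
            make_params(sigma_r=0.0)

    def test_prior_config_yaml_round_trip(self, tmp_path):
        config = rb.PriorConfig(
            coef=rb.PriorSpec("student_t", 0.0, 1.0, df=5),
            sigma=rb.PriorSpec("half_normal", 0.0, 1.5),
        )
        path = tmp_path / "priors.yaml"
        config.to_yaml(path)
        assert rb.PriorConfig.from_yaml(path) == config

    def test_sigma_prior_must_be_positive_family(self):
        with pytest.raises(ValueError, match="half-line"):
            rb.PriorConfig(sigma=rb.PriorSpec("normal", 0.0, 2.5))


class TestLogPosterior:
    def test_is_likelihood_plus_prior(self, small_dataset):
        params = make_params(n=3, r=np.array([0.3, -0.4, 0.1]))
        assert rb.log_posterior(params, small_dataset) == pytest.approx(
            rb.log_likelihood(params, small_dataset) + rb.log_prior(params)
        )

    def test_invariant_under_consistent_relabeling(self, small_dataset):
        perm = np.array([2, 0, 1])
        params = make_params(n=3, r=np.array([0.3, -0.4, 0.1]))
        permuted_data = rb.AnalysisDataset(
            participants=[small_dataset.participants[j] for j in perm],
            cia=small_dataset.cia[perm],
            y_async=small_dataset.y_async[perm],
            y_sync=small_dataset.y_sync[perm],
            n_categories=7,
        )
        permuted_params = make_params(n=3, r=params.r[perm])
        assert rb.log_posterior(permuted_params, permuted_data) == pytest.approx(
            rb.log_posterior(params, small_dataset), rel=1e-12
        )
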