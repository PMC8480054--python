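"""Tests for the Gibbs sampler: conjugate-update oracles, hyperparameter
defaults, bookkeeping, reproducibility and short-run recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

from intakequant import (ComponentParams, GeneratorConfig, Hyperparameters,
                         InterventionData, MeasurementParams,
                         default_hyperparameters, fit,
                         generate_intervention_study, summarize_chain)
from intakequant.gating import GatingParameters, gating_probs_matrix
from intakequant.sampler import (ModelState, intake_conditional,
                                 update_component_variances, update_intakes,
                                 update_labels, update_measurement)


def _null_gating(P, D):
    return GatingParameters(np.linspace(-1, 1, D - 1) if D > 1 else np.empty(0),
                            np.zeros(P), np.zeros(P), np.ones(P))


def _state_for(data, params, theta2, z=None, c=None):
    return ModelState(params=params, comp=ComponentParams(theta2),
                      gating=_null_gating(data.P, data.D),
                      z=data.quantities.astype(float) if z is None else z,
                      c=data.dose_index.copy() if c is None else c)


class TestDefaultHyperparameters:
    def test_noiseless_line_recovered_exactly(self):
        x = np.repeat([80.0, 160.0, 320.0], 5)
        y = 2.0 + 0.5 * x
        data = InterventionData(x, np.column_stack([y, y]))
        hyper = default_hyperparameters(data)
        np.testing.assert_allclose(hyper.alpha_mean, [2.0, 2.0], atol=1e-9)
        np.testing.assert_allclose(hyper.beta_mean, [0.5, 0.5], atol=1e-12)

    def test_component_scale_formula(self):
        data, _ = generate_intervention_study(GeneratorConfig(seed=0))
        hyper = default_hyperparameters(data)
        np.testing.assert_allclose(hyper.theta2_scale,
                                   (np.array([80.0, 160.0, 320.0]) / 3) ** 2)
        assert hyper.sigma2_shape == 2.0 and hyper.theta2_shape == 2.0

    def test_deterministic(self):
        data, _ = generate_intervention_study(GeneratorConfig(seed=1))
        h1, h2 = default_hyperparameters(data), default_hyperparameters(data)
        np.testing.assert_array_equal(h1.alpha_mean, h2.alpha_mean)
        np.testing.assert_array_equal(h1.sigma2_scale, h2.sigma2_scale)


class TestUpdateLabels:
    def test_single_component(self):
        data, _ = generate_intervention_study(
            GeneratorConfig(dose_levels=(100.0,), group_sizes=(10,),
                            seed=2))
        params = MeasurementParams(*(np.ones(3),) * 3)
        state = _state_for(data, params, np.array([25.0]))
        labels = update_labels(state, data, np.random.default_rng(0))
        np.testing.assert_array_equal(labels, np.zeros(10, dtype=int))

    def test_mode_at_own_component(self):
        """With uniform weights and equal variances, z at a component center
        allocates to that component most often."""
        x = np.array([80.0, 160.0, 320.0])
        data = InterventionData(np.repeat(x, 2), np.ones((6, 2)))
        params = MeasurementParams([0, 0], [1, 1], [1, 1])
        state = _state_for(data, params, np.full(3, 30.0 ** 2),
                           z=np.full(6, 160.0))
        rng = np.random.default_rng(3)
        draws = np.array([update_labels(state, data, rng)
                          for _ in range(400)])
        freq = np.bincount(draws.ravel(), minlength=3) / draws.size
        assert np.argmax(freq) == 1

    def test_allocation_probabilities_match_oracle(self):
        """Empirical allocation frequencies against probabilities computed
        from scipy's truncated normal density (independent route)."""
        x = np.array([5.0, 10.0, 20.0])
        y = np.array([[1.0, 2.0]])
        data = InterventionData(np.array([5.0, 10.0, 20.0]), np.ones((3, 2)))
        theta2 = np.array([4.0, 9.0, 25.0])
        pi = np.array([0.2, 0.5, 0.3])
        z = 8.0
        dens = np.array([stats.truncnorm.pdf(z, -m / s, np.inf, loc=m, scale=s)
                         for m, s in zip(x, np.sqrt(theta2))])
        oracle = pi * dens / np.sum(pi * dens)

        params = MeasurementParams([0, 0], [1, 1], [1, 1])
        state = _state_for(data, params, theta2, z=np.full(3, z))
        rng = np.random.default_rng(4)
        log_pi = np.log(np.tile(pi, (3, 1)))
        draws = np.array([update_labels(state, data, rng, log_pi)
                          for _ in range(4000)])
        freq = np.bincount(draws.ravel(), minlength=3) / draws.size
        np.testing.assert_allclose(freq, oracle, atol=0.02)


class TestUpdateIntakes:
    def test_likelihood_dominates_small_sigma(self):
        x = np.array([100.0])
        y = np.array([[50.0]])
        with pytest.warns(UserWarning):
            data = InterventionData(x, y)
        params = MeasurementParams([10.0], [2.0], [1e-8])
        state = _state_for(data, params, np.array([100.0]))
        z = update_intakes(state, data, np.random.default_rng(5))
        assert z[0] == pytest.approx((50.0 - 10.0) / 2.0, rel=1e-3)

    def test_prior_dominates_small_theta(self):
        x = np.array([100.0])
        y = np.array([[500.0, 500.0]])
        data = InterventionData(x, y)
        params = MeasurementParams([0, 0], [1, 1], [1e6, 1e6])
        state = _state_for(data, params, np.array([1e-6]))
        z = update_intakes(state, data, np.random.default_rng(6))
        assert z[0] == pytest.approx(100.0, abs=0.01)

    @pytest.mark.parametrize("seed", range(8))
    def test_conditional_moments_match_quadrature(self, seed):
        """Closed-form truncated-normal conditional vs direct quadrature of
        the product density on (0, inf)."""
        rng = np.random.default_rng(seed)
        P = int(rng.integers(1, 4))
        params = MeasurementParams(rng.normal(scale=5, size=P),
                                   rng.uniform(0.2, 2.0, P),
                                   rng.uniform(0.5, 50.0, P))
        x_c = rng.uniform(1.0, 30.0)
        theta2_c = rng.uniform(0.5, 100.0)
        ztrue = rng.uniform(0.5, 30.0)
        y = params.alpha + params.beta * ztrue + rng.normal(size=P)

        m, v = intake_conditional(y, params, x_c, theta2_c)
        m = float(m[0])
        sd = np.sqrt(v)
        a = -m / sd
        mean_cf, var_cf = stats.truncnorm.stats(a, np.inf, loc=m, scale=sd,
                                                moments="mv")

        def dens(z):
            ll = -0.5 * np.sum((y - params.alpha - params.beta * z) ** 2
                               / params.sigma2)
            pr = -0.5 * (z - x_c) ** 2 / theta2_c
            return np.exp(ll + pr)

        lo, hi = max(float(m) - 12 * sd, 0.0), float(m) + 12 * sd
        norm, _ = integrate.quad(dens, lo, hi, limit=200)
        m1, _ = integrate.quad(lambda z: z * dens(z), lo, hi, limit=200)
        m2, _ = integrate.quad(lambda z: z * z * dens(z), lo, hi, limit=200)
        mean_q = m1 / norm
        var_q = m2 / norm - mean_q ** 2
        assert mean_q == pytest.approx(float(mean_cf), rel=1e-3, abs=1e-3)
        assert var_q == pytest.approx(float(var_cf), rel=1e-3, abs=1e-3)


class TestUpdateMeasurement:
    def test_flat_prior_limit_matches_ols(self):
        rng = np.random.default_rng(7)
        n = 300
        z = rng.uniform(10, 100, n)
        y = 3.0 + 0.8 * z + rng.normal(scale=0.5, size=n)
        data = InterventionData(np.full(n, 50.0), np.column_stack([y, y]))
        hyper = Hyperparameters(
            alpha_mean=[0.0, 0.0], alpha_var=[1e8, 1e8],
            beta_mean=[1.0, 1.0], beta_var=[1e8, 1e8],
            sigma2_shape=2.0, sigma2_scale=[1e-6, 1e-6],
            theta2_shape=2.0, theta2_scale=[1.0])
        params = MeasurementParams([0, 0], [1, 1], [1e-8, 1e-8])
        state = _state_for(data, params, np.array([1.0]),
                           z=z, c=np.zeros(n, dtype=int))
        new = update_measurement(state, data, hyper, np.random.default_rng(8))
        slope, intercept = np.polyfit(z, y, 1)
        # with sigma2 ~ 1e-8 the conditional is essentially a point mass at
        # the flat-prior posterior mean, i.e. the OLS solution
        assert new.alpha[0] == pytest.approx(intercept, abs=1e-4)
        assert new.beta[0] == pytest.approx(slope, abs=1e-4)

    def test_tight_prior_pins_to_prior_mean(self):
        rng = np.random.default_rng(9)
        n = 50
        z = rng.uniform(10, 100, n)
        y = rng.normal(size=n)
        hyper = Hyperparameters(
            alpha_mean=[5.0], alpha_var=[1e-10],
            beta_mean=[2.0], beta_var=[1e-10],
            sigma2_shape=2.0, sigma2_scale=[1.0],
            theta2_shape=2.0, theta2_scale=[1.0])
        with pytest.warns(UserWarning):
            data = InterventionData(np.full(n, 50.0), y[:, None])
        params = MeasurementParams([0.0], [1.0], [1.0])
        state = _state_for(data, params, np.array([1.0]),
                           z=z, c=np.zeros(n, dtype=int))
        new = update_measurement(state, data, hyper, np.random.default_rng(10))
        assert new.alpha[0] == pytest.approx(5.0, abs=1e-3)
        assert new.beta[0] == pytest.approx(2.0, abs=1e-3)

    def test_sigma2_posterior_concentration(self):
        """Zero residuals: sigma2 ~ IG(shape + n/2, scale); the mean of many
        draws matches the inverse-gamma mean formula."""
        n = 100
        z = np.linspace(1, 50, n)
        alpha0, beta0 = 2.0, 0.5
        y = alpha0 + beta0 * z
        with pytest.warns(UserWarning):
            data = InterventionData(np.full(n, 25.0), y[:, None])
        hyper = Hyperparameters(
            alpha_mean=[alpha0], alpha_var=[1e-12],
            beta_mean=[beta0], beta_var=[1e-12],
            sigma2_shape=2.0, sigma2_scale=[3.0],
            theta2_shape=2.0, theta2_scale=[1.0])
        params = MeasurementParams([alpha0], [beta0], [1.0])
        state = _state_for(data, params, np.array([1.0]),
                           z=z, c=np.zeros(n, dtype=int))
        rng = np.random.default_rng(11)
        draws = np.array([update_measurement(state, data, hyper, rng).sigma2[0]
                          for _ in range(2000)])
        expected = 3.0 / (2.0 + n / 2 - 1)
        assert draws.mean() == pytest.approx(expected, rel=0.05)


class TestUpdateComponentVariances:
    def _setup(self, z, c, x, theta2, shape=2.0, scale=(100.0,),
               quantities=None):
        n = z.shape[0]
        data = InterventionData(x[c] if quantities is None else quantities,
                                np.ones((n, 2)))
        hyper = Hyperparameters(
            alpha_mean=[0, 0], alpha_var=[1, 1], beta_mean=[1, 1],
            beta_var=[1, 1], sigma2_shape=2.0, sigma2_scale=[1, 1],
            theta2_shape=shape, theta2_scale=np.asarray(scale, dtype=float))
        params = MeasurementParams([0, 0], [1, 1], [1, 1])
        state = _state_for(data, params, np.asarray(theta2, dtype=float),
                           z=z, c=c)
        return state, data, hyper

    def test_empty_component_draws_from_prior(self):
        x = np.array([10.0, 1000.0])
        z = np.full(20, 10.0)
        c = np.zeros(20, dtype=int)   # component 2 has no members
        quantities = np.r_[np.full(19, 10.0), [1000.0]]
        state, data, hyper = self._setup(z, c, x, [4.0, 4.0], shape=3.0,
                                         scale=(100.0, 50.0),
                                         quantities=quantities)
        rng = np.random.default_rng(12)
        draws = np.array([update_component_variances(state, data, hyper,
                                                     rng).theta2[1]
                          for _ in range(3000)])
        assert draws.mean() == pytest.approx(50.0 / (3.0 - 1), rel=0.1)

    def test_concentration_at_zero_spread(self):
        n = 400
        x = np.array([1000.0])
        z = np.full(n, 1000.0)
        c = np.zeros(n, dtype=int)
        state, data, hyper = self._setup(z, c, x, [4.0], shape=2.0,
                                         scale=(100.0,))
        rng = np.random.default_rng(13)
        draws = np.array([update_component_variances(state, data, hyper,
                                                     rng).theta2[0]
                          for _ in range(2000)])
        expected = 100.0 / (2.0 + n / 2 - 1)
        assert draws.mean() == pytest.approx(expected, rel=0.05)

    def test_metropolis_acceptance_far_from_boundary(self):
        """When x_d >> theta_d the truncation correction vanishes and the
        proposal is accepted essentially always (value changes every call)."""
        rng = np.random.default_rng(14)
        n = 50
        x = np.array([1000.0])
        z = 1000.0 + rng.normal(scale=5.0, size=n)
        c = np.zeros(n, dtype=int)
        state, data, hyper = self._setup(z, c, x, [25.0])
        changed = 0
        trials = 500
        for _ in range(trials):
            new = update_component_variances(state, data, hyper, rng)
            changed += new.theta2[0] != state.comp.theta2[0]
        assert changed / trials > 0.99


class TestSummarizeChain:
    def test_basic_examples(self):
        assert summarize_chain([1.0, 2.0, 3.0])[0] == 2.0
        med, sd, lo, hi = summarize_chain(np.full(10, 7.0))
        assert (med, sd, lo, hi) == (7.0, 0.0, 7.0, 7.0)

    def test_normal_quantiles(self):
        draws = np.random.default_rng(15).normal(size=10 ** 5)
        _, _, lo, hi = summarize_chain(draws)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_empty_chain_errors(self):
        with pytest.raises(ValueError):
            summarize_chain([])


class TestFit:
    def test_chain_bookkeeping_and_invariants(self, small_fitted_model):
        m = small_fitted_model
        S = m.meta["niter"] - m.meta["burnin"]
        for name in ("alpha", "beta", "sigma2", "theta2", "zeta", "w", "z"):
            assert m.chains[name].shape[0] == S
        assert np.all(m.chains["z"] > 0)
        assert np.all(m.chains["sigma2"] > 0)
        assert np.all(m.chains["theta2"] > 0)
        assert np.all(np.diff(m.chains["zeta"], axis=1) > 0)
        # the posterior median always lies inside its own credible interval
        s = m.summaries
        assert np.all(s["ci_low"] <= s["median"] + 1e-12)
        assert np.all(s["median"] <= s["ci_high"] + 1e-12)

    def test_same_seed_bitwise_reproducible(self, default_study):
        data, _ = default_study
        a = fit(data, niter=300, burnin=100, seed=42)
        b = fit(data, niter=300, burnin=100, seed=42)
        for name in a.chains:
            np.testing.assert_array_equal(a.chains[name], b.chains[name])
        assert a.summaries.equals(b.summaries)

    def test_noiseless_limit_recovers_intakes(self):
        config = GeneratorConfig(sigma=(0.001, 0.001, 0.001), intake_sd=0.0,
                                 seed=16)
        data, truth = generate_intervention_study(config)
        model = fit(data, niter=400, burnin=150, seed=17)
        med = np.median(model.chains["z"], axis=0)
        np.testing.assert_allclose(med, truth["z"], rtol=0.01)

    def test_argument_validation(self, default_study):
        data, _ = default_study
        with pytest.raises(ValueError):
            fit(data, niter=100, burnin=100)
        with pytest.raises(ValueError):
            fit(data, niter=100, burnin=-1)
        with pytest.raises(TypeError):
            fit(np.ones((5, 3)), niter=100, burnin=10)

    def test_short_chain_warns(self, default_study):
        data, _ = default_study
        with pytest.warns(UserWarning, match="retained draws"):
            fit(data, niter=60, burnin=10, seed=18)
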