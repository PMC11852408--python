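import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from varmeta.core_model import (
    BatchEffects,
    HierarchicalDataset,
    Measurement,
    PopulationParams,
    PriorConfig,
    ProductEffects,
    log_posterior_unnormalized,
    log_prior,
    log_random_effect,
    loglik_multi_cycle,
    loglik_multi_cycle_marginal,
    loglik_single_cycle,
)

LOG_2PI = math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestMeasurement:
    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            Measurement("p", "b", None, float("nan"))
        with pytest.raises(ValueError, match="finite"):
            Measurement("p", "b", "c", float("inf"))

    def test_duplicate_keys_rejected(self):
        rows = [Measurement("p", "b", "c", 0.0), Measurement("p", "b", "c", 1.0)]
        with pytest.raises(ValueError, match="duplicate"):
            HierarchicalDataset(rows)


class TestHierarchicalDataset:
    def test_mode_inference(self):
        data = HierarchicalDataset(
            [
                Measurement("s", "b1", None, 0.0),
                Measurement("s", "b2", None, 1.0),
                Measurement("m", "b1", "c1", 0.0),
                Measurement("m", "b1", "c2", 1.0),
            ]
        )
        assert data.mode("s") == "single_cycle"
        assert data.mode("m") == "multi_cycle"

    def test_declared_mode_must_agree(self):
        rows = [
            Measurement("p", "b1", "c1", 0.0),
            Measurement("p", "b1", "c2", 1.0),
        ]
        with pytest.raises(ValueError, match="disagrees"):
            HierarchicalDataset(rows, modes={"p": "single_cycle"})

    def test_single_observation_warns(self):
        with pytest.warns(UserWarning, match="single observation"):
            HierarchicalDataset([Measurement("p", "b1", None, 0.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            HierarchicalDataset([])


class TestProductEffects:
    def test_variance_split_enforced(self):
        ProductEffects(mu_i=0.0, sigma_i=math.sqrt(2.0), tau_i=1.0, nu_i=1.0)
        with pytest.raises(ValueError, match="violated"):
            ProductEffects(mu_i=0.0, sigma_i=1.5, tau_i=1.0, nu_i=1.0)

    def test_from_proportion_preserves_split(self):
        eff = ProductEffects.from_proportion(0.0, 1.3, 0.27)
        assert eff.tau_i**2 + eff.nu_i**2 == pytest.approx(
            eff.sigma_i**2, rel=1e-10
        )
        assert eff.p_i == pytest.approx(0.27, rel=1e-12)

    @given(
        sigma=st.floats(0.01, 50.0),
        p=st.floats(1e-9, 1.0 - 1e-9),
        mu=st.floats(-10, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_split_invariant_property(self, sigma, p, mu):
        eff = ProductEffects.from_proportion(mu, sigma, p)
        assert abs(eff.tau_i**2 + eff.nu_i**2 - sigma**2) <= 1e-10 * sigma**2

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ProductEffects(mu_i=0.0, sigma_i=0.0)

    def test_single_cycle_has_no_proportion(self):
        assert ProductEffects(mu_i=0.0, sigma_i=1.0).p_i is None


def test_prior_config_defaults_and_validation():
    cfg = PriorConfig()
    assert cfg.mu_prior_sd == 1.0
    assert cfg.sigma_prior_sd == 1.0
    with pytest.raises(ValueError):
        PriorConfig(mu_prior_sd=0.0)


# ---------------------------------------------------------------------------
# log prior
# ---------------------------------------------------------------------------


class TestLogPrior:
    def test_reference_point(self):
        # mu=0, sigma=1, no products: standard normal at mode plus
        # half-normal at 1, each evaluated from the closed-form log pdf
        expected = -0.5 * LOG_2PI + (math.log(2) - 0.5 * LOG_2PI - 0.5)
        got = log_prior(PopulationParams(0.0, 1.0), [], PriorConfig())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_doubling_mu_prior_sd_changes_by_log2(self):
        pop = PopulationParams(0.0, 1.0)
        base = log_prior(pop, [], PriorConfig(mu_prior_sd=1.0))
        wide = log_prior(pop, [], PriorConfig(mu_prior_sd=2.0))
        assert wide - base == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_widening_priors_decreases_mode_density(self):
        pop = PopulationParams(0.0, 1e-6)
        values = [
            log_prior(pop, [], PriorConfig(mu_prior_sd=s, sigma_prior_sd=s))
            for s in (1, 2, 3, 4, 5)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_prior(PopulationParams(0.0, 0.0), [], PriorConfig())

    def test_matches_scipy(self):
        prior = PriorConfig(mu_prior_sd=1.5, sigma_prior_sd=0.7,
                            product_mean_prior_sd=3.0)
        pop = PopulationParams(0.4, 0.9)
        effects = [
            ProductEffects(mu_i=-0.3, sigma_i=1.1),
            ProductEffects.from_proportion(0.2, 0.8, 0.4),
        ]
        expected = (
            stats.norm.logpdf(0.4, 0, 1.5)
            + stats.halfnorm.logpdf(0.9, 0, 0.7)
            + stats.norm.logpdf(-0.3, 0, 3.0)
            + stats.norm.logpdf(0.2, 0, 3.0)
            + stats.uniform.logpdf(0.4, 0, 1)
        )
        assert log_prior(pop, effects, prior) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


class TestSingleCycleLikelihood:
    def test_standard_normal_at_mode(self):
        eff = ProductEffects(mu_i=0.0, sigma_i=1.0)
        assert loglik_single_cycle([0.0], eff) == pytest.approx(
            -0.5 * LOG_2PI, abs=1e-12
        )

    def test_two_points_hand_sum(self):
        # log N(0|0,1) + log N(1|0,1) = -ln(2*pi) - 1/2
        eff = ProductEffects(mu_i=0.0, sigma_i=1.0)
        assert loglik_single_cycle([0.0, 1.0], eff) == pytest.approx(
            -LOG_2PI - 0.5, abs=1e-12
        )

    @given(
        shift=st.floats(-50, 50),
        mu=st.floats(-5, 5),
        sigma=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_location_invariance(self, shift, mu, sigma):
        y = np.array([0.3, -1.2, 2.0])
        a = loglik_single_cycle(y, ProductEffects(mu_i=mu, sigma_i=sigma))
        b = loglik_single_cycle(
            y + shift, ProductEffects(mu_i=mu + shift, sigma_i=sigma)
        )
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            loglik_single_cycle([], ProductEffects(mu_i=0.0, sigma_i=1.0))


class TestMultiCycleLikelihood:
    def test_single_point_at_mode(self):
        eff = ProductEffects(
            mu_i=0.0, sigma_i=math.sqrt(2.0), tau_i=1.0, nu_i=1.0
        )
        got = loglik_multi_cycle([[0.0]], eff, BatchEffects([0.0]))
        assert got == pytest.approx(-LOG_2PI, abs=1e-12)

    def test_density_decreases_in_tau_at_mode(self):
        values = []
        for tau in (0.5, 1.0, 2.0, 4.0):
            sigma = math.sqrt(tau**2 + 1.0)
            eff = ProductEffects(mu_i=0.0, sigma_i=sigma, tau_i=tau, nu_i=1.0)
            values.append(loglik_multi_cycle([[0.0]], eff, BatchEffects([0.0])))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_boundary_rejected(self):
        eff = ProductEffects(mu_i=0.0, sigma_i=1.0, tau_i=0.0, nu_i=1.0)
        with pytest.raises(ValueError, match="> 0"):
            loglik_multi_cycle([[0.0]], eff, BatchEffects([0.0]))

    def test_marginal_matches_closed_form_mvn(self):
        # per-batch covariance nu^2 I + tau^2 J
        eff = ProductEffects.from_proportion(0.3, 1.2, 0.4)
        batches = [np.array([0.1, 0.9]), np.array([-0.4, 0.2, 1.3])]
        got = loglik_multi_cycle_marginal(batches, eff)
        expected = 0.0
        for y in batches:
            cov = eff.nu_i**2 * np.eye(y.size) + eff.tau_i**2 * np.ones(
                (y.size, y.size)
            )
            expected += stats.multivariate_normal.logpdf(
                y, mean=np.full(y.size, eff.mu_i), cov=cov
            )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_marginal_matches_monte_carlo_of_hierarchical_form(self, rng):
        # integrate the batch mean out by brute-force simulation on a
        # 2-cycle toy batch and compare with the closed form
        eff = ProductEffects.from_proportion(0.3, 1.2, 0.4)
        y = np.array([0.1, 0.9])
        n_mc = 400_000
        mu_ij = rng.normal(eff.mu_i, eff.tau_i, size=n_mc)
        logliks = (
            stats.norm.logpdf(y[0], mu_ij, eff.nu_i)
            + stats.norm.logpdf(y[1], mu_ij, eff.nu_i)
        )
        mc = np.logaddexp.reduce(logliks) - math.log(n_mc)
        exact = loglik_multi_cycle_marginal([y], eff)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_batch_mean_count_checked(self):
        eff = ProductEffects.from_proportion(0.0, 1.0, 0.5)
        with pytest.raises(ValueError, match="batch means"):
            loglik_multi_cycle([[0.0], [1.0]], eff, BatchEffects([0.0]))


# ---------------------------------------------------------------------------
# random effect
# ---------------------------------------------------------------------------


class TestLogRandomEffect:
    def test_at_population_median(self):
        mu, sigma = 0.25, 0.7
        eff = ProductEffects(mu_i=0.0, sigma_i=math.exp(mu))
        expected = -0.5 * LOG_2PI - math.log(sigma) - mu
        got = log_random_effect(eff, PopulationParams(mu, sigma))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_standard_point(self):
        eff = ProductEffects(mu_i=0.0, sigma_i=1.0)
        got = log_random_effect(eff, PopulationParams(0.0, 1.0))
        assert got == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_matches_scipy_lognorm(self):
        pop = PopulationParams(0.1, 0.4)
        for s in (0.2, 0.9, 1.7, 3.0):
            eff = ProductEffects(mu_i=0.0, sigma_i=s)
            expected = stats.lognorm.logpdf(s, pop.sigma, scale=math.exp(pop.mu))
            assert log_random_effect(eff, pop) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self):
        pop = PopulationParams(0.1, 0.4)

        def density(s):
            return math.exp(
                log_random_effect(ProductEffects(mu_i=0.0, sigma_i=s), pop)
            )

        total, err = integrate.quad(density, 1e-12, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_non_positive_sigma_i_rejected(self):
        with pytest.raises(ValueError):
            log_random_effect(
                ProductEffects(mu_i=0.0, sigma_i=1.0), PopulationParams(0.0, 0.0)
            )


# ---------------------------------------------------------------------------
# assembled posterior
# ---------------------------------------------------------------------------


class TestLogPosteriorUnnormalized:
    def _components(self, mixed_dataset, rng):
        pop = PopulationParams(0.05, 0.5)
        prior = PriorConfig()
        effects, batch_means = {}, {}
        for pid in mixed_dataset.product_ids:
            mu_i = float(rng.normal())
            sigma_i = float(np.exp(rng.normal(0.1, 0.3)))
            if mixed_dataset.mode(pid) == "multi_cycle":
                effects[pid] = ProductEffects.from_proportion(
                    mu_i, sigma_i, float(rng.uniform(0.2, 0.8))
                )
                nb = len(mixed_dataset.batch_ids(pid))
                batch_means[pid] = BatchEffects(rng.normal(size=nb))
            else:
                effects[pid] = ProductEffects(mu_i=mu_i, sigma_i=sigma_i)
        return pop, prior, effects, batch_means

    def test_additive_decomposition_exact(self, mixed_dataset, rng):
        pop, prior, effects, batch_means = self._components(mixed_dataset, rng)
        total = log_posterior_unnormalized(
            mixed_dataset, pop, effects, batch_means, prior
        )
        manual = log_prior(pop, list(effects.values()), prior)
        for pid in mixed_dataset.product_ids:
            manual += log_random_effect(effects[pid], pop)
            if mixed_dataset.mode(pid) == "single_cycle":
                manual += loglik_single_cycle(
                    mixed_dataset.single_cycle_values(pid), effects[pid]
                )
            else:
                manual += loglik_multi_cycle(
                    mixed_dataset.batch_values(pid), effects[pid], batch_means[pid]
                )
        assert total == pytest.approx(manual, rel=1e-12)

    def test_reference_toy_sum(self):
        # one product, y={0}, everything at its 0/1 reference value:
        # the three component examples summed by hand
        data = HierarchicalDataset([Measurement("p", "b1", None, 0.0),
                                    Measurement("p", "b2", None, 0.0)])
        pop = PopulationParams(0.0, 1.0)
        prior = PriorConfig()
        eff = {"p": ProductEffects(mu_i=0.0, sigma_i=1.0)}
        expected = (
            log_prior(pop, [eff["p"]], prior)
            + (-0.5 * LOG_2PI)  # random effect at sigma_i=1
            + 2 * (-0.5 * LOG_2PI)  # two standard normal points at mode
        )
        got = log_posterior_unnormalized(data, pop, eff, {}, prior)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_mode_mismatch_rejected(self, single_cycle_dataset):
        data, _ = single_cycle_dataset
        pop = PopulationParams(0.1, 0.4)
        effects = {
            pid: ProductEffects.from_proportion(0.0, 1.0, 0.5)
            for pid in data.product_ids
        }
        with pytest.raises(ValueError, match="mode"):
            log_posterior_unnormalized(data, pop, effects, {}, PriorConfig())

    def test_location_invariance_of_total(self, single_cycle_dataset):
        data, _ = single_cycle_dataset
        pop = PopulationParams(0.1, 0.4)
        prior = PriorConfig(product_mean_prior_sd=1e9)  # flat product means
        effects = {
            pid: ProductEffects(mu_i=0.3, sigma_i=1.2) for pid in data.product_ids
        }
        base = log_posterior_unnormalized(data, pop, effects, {}, prior)
        shift = 7.5
        pid0 = data.product_ids[0]
        shifted_rows = [
            Measurement(
                m.product_id,
                m.batch_id,
                m.cycle_id,
                m.value + (shift if m.product_id == pid0 else 0.0),
            )
            for m in data.measurements
        ]
        shifted_data = HierarchicalDataset(shifted_rows)
        shifted_effects = dict(effects)
        shifted_effects[pid0] = ProductEffects(mu_i=0.3 + shift, sigma_i=1.2)
        moved = log_posterior_unnormalized(
            shifted_data, pop, shifted_effects, {}, prior
        )
        assert moved == pytest.approx(base, rel=1e-9)
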