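"""EM fitting: E-step, hyperprior, M-step gradient, monotone convergence, recovery."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from dmmix import (
    CountMatrix,
    DirichletComponent,
    FitConfig,
    Hyperprior,
    MixtureModel,
    expected_log_posterior,
    fit_dmm,
    log_hyperprior,
    optimize_component,
    responsibilities,
    update_weights,
)
from dmmix.core import log_component_evidence, log_dataset_evidence
from dmmix.em import Responsibilities, _component_objective
from dmmix.simulate import k1_benchmark_spec, k2_benchmark_spec, recovery_report, sample_dataset


class TestResponsibilities:
    def test_single_component_all_one(self, toy_counts):
        m = MixtureModel(
            components=[DirichletComponent.from_alpha([1.0, 1.0, 1.0])], weights=np.array([1.0])
        )
        z = responsibilities(toy_counts, m).z
        np.testing.assert_allclose(z, 1.0)

    def test_identical_components_uniform(self, toy_counts):
        c = DirichletComponent.from_alpha([2.0, 1.0, 3.0])
        m = MixtureModel(components=[c, c, c], weights=np.full(3, 1 / 3))
        z = responsibilities(toy_counts, m).z
        np.testing.assert_allclose(z, 1 / 3)

    def test_hand_computed_bayes_ratio(self):
        X = CountMatrix(counts=np.array([[5, 0]]))
        c1 = DirichletComponent.from_alpha([8.0, 2.0])
        c2 = DirichletComponent.from_alpha([2.0, 8.0])
        m = MixtureModel(components=[c1, c2], weights=np.array([0.9, 0.1]))
        l1 = log_component_evidence(np.array([5, 0]), c1, include_coefficient=False)
        l2 = log_component_evidence(np.array([5, 0]), c2, include_coefficient=False)
        expected = 0.9 * np.exp(l1) / (0.9 * np.exp(l1) + 0.1 * np.exp(l2))
        z = responsibilities(X, m).z
        assert z[0, 0] == pytest.approx(expected, rel=1e-12)


class TestLogHyperprior:
    def test_single_parameter_value(self):
        """One parameter at lam=0 under Gamma(0.1, 0.1): direct evaluation."""
        m = MixtureModel(
            components=[DirichletComponent(lam=np.array([0.0]))], weights=np.array([1.0])
        )
        hp = Hyperprior(eta=0.1, nu=0.1)
        expected = 0.1 * np.log(0.1) - gammaln(0.1) - 0.1
        assert log_hyperprior(m, hp) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-2.58297, abs=1e-4)

    def test_density_integrates_to_one(self):
        hp = Hyperprior(eta=1.0, nu=1.0)

        def dens(lam):
            m = MixtureModel(
                components=[DirichletComponent(lam=np.array([lam]))], weights=np.array([1.0])
            )
            return np.exp(log_hyperprior(m, hp))

        val, _ = integrate.quad(dens, -40, 10)
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_scales_linearly_with_parameters(self):
        hp = Hyperprior(eta=0.5, nu=0.2)
        one = MixtureModel(
            components=[DirichletComponent(lam=np.zeros(1))], weights=np.array([1.0])
        )
        many = MixtureModel(
            components=[DirichletComponent(lam=np.zeros(4)) for _ in range(3)],
            weights=np.full(3, 1 / 3),
        )
        assert log_hyperprior(many, hp) == pytest.approx(12 * log_hyperprior(one, hp))


class TestExpectedLogPosterior:
    def test_k1_equals_dataset_evidence_plus_hyperprior(self, toy_counts):
        m = MixtureModel(
            components=[DirichletComponent.from_alpha([1.0, 2.0, 3.0])], weights=np.array([1.0])
        )
        hp = Hyperprior()
        z = Responsibilities(z=np.ones((toy_counts.n_samples, 1)))
        assert expected_log_posterior(toy_counts, z, m, hp) == pytest.approx(
            log_dataset_evidence(toy_counts, m) + log_hyperprior(m, hp)
        )

    def test_e_step_optimality(self, toy_counts):
        """The E-step responsibilities maximise the bound at fixed parameters."""
        m = MixtureModel(
            components=[
                DirichletComponent.from_alpha([1.0, 2.0, 3.0]),
                DirichletComponent.from_alpha([4.0, 1.0, 1.0]),
            ],
            weights=np.array([0.4, 0.6]),
        )
        hp = Hyperprior()
        z_opt = responsibilities(toy_counts, m)
        best = expected_log_posterior(toy_counts, z_opt, m, hp)
        rng = np.random.default_rng(1)
        for _ in range(5):
            z_rand = Responsibilities(z=rng.dirichlet(np.ones(2), size=toy_counts.n_samples))
            assert expected_log_posterior(toy_counts, z_rand, m, hp) <= best + 1e-9


class TestUpdateWeights:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (np.array([[1.0, 0.0], [1.0, 0.0]]), [1.0, 0.0]),
            (np.array([[0.5, 0.5], [0.5, 0.5]]), [0.5, 0.5]),
            (np.array([[1.0, 0.0], [0.5, 0.5]]), [0.75, 0.25]),
        ],
    )
    def test_column_means(self, z, expected):
        np.testing.assert_allclose(update_weights(Responsibilities(z=z)), expected)


class TestOptimizeComponent:
    def test_gradient_at_optimum(self, toy_counts):
        cfg = FitConfig(optimizer_grad_tol=1e-5)
        lam0 = np.zeros(3)
        z_col = np.ones(toy_counts.n_samples)
        lam, ok = optimize_component(toy_counts, z_col, lam0, cfg.hyperprior, cfg)
        assert ok
        _, grad = _component_objective(
            lam, toy_counts.counts.astype(float), toy_counts.row_totals.astype(float),
            z_col, cfg.hyperprior,
        )
        assert np.max(np.abs(grad)) <= 1e-5

    def test_analytic_gradient_matches_finite_differences(self, toy_counts):
        cfg = FitConfig()
        rng = np.random.default_rng(3)
        lam = rng.normal(size=3)
        z_col = rng.uniform(0.2, 1.0, size=toy_counts.n_samples)
        counts = toy_counts.counts.astype(float)
        totals = toy_counts.row_totals.astype(float)
        f0, g = _component_objective(lam, counts, totals, z_col, cfg.hyperprior)
        h = 1e-6
        for j in range(3):
            d = np.zeros(3)
            d[j] = h
            fp, _ = _component_objective(lam + d, counts, totals, z_col, cfg.hyperprior)
            fm, _ = _component_objective(lam - d, counts, totals, z_col, cfg.hyperprior)
            assert g[j] == pytest.approx((fp - fm) / (2 * h), rel=1e-4, abs=1e-6)

    def test_taxon_exchange_symmetry(self):
        X = CountMatrix(counts=np.array([[5, 5], [3, 3], [7, 7]]))
        cfg = FitConfig()
        lam, _ = optimize_component(X, np.ones(3), np.zeros(2), cfg.hyperprior, cfg)
        assert lam[0] == pytest.approx(lam[1], abs=1e-6)

    def test_recovers_known_dirichlet_multinomial_mean(self):
        from dataclasses import replace

        spec = replace(k1_benchmark_spec(seed=11), n_samples=300)
        X, _ = sample_dataset(spec)
        cfg = FitConfig()
        lam, _ = optimize_component(
            X, np.ones(X.n_samples), np.log(np.full(X.n_taxa, 0.5)), cfg.hyperprior, cfg
        )
        m_hat = np.exp(lam) / np.exp(lam).sum()
        assert np.abs(m_hat - spec.means[0]).sum() <= 0.02


class TestFitDMM:
    def test_lower_bound_monotone(self, toy_fit):
        fit, _ = toy_fit
        trace = np.array(fit.lower_bound_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_k1_parameter_recovery(self):
        """S=10, N=100, theta=50 single component: mean within 0.03 L1, theta within 25%."""
        spec = k1_benchmark_spec(seed=5)
        X, truth = sample_dataset(spec)
        fit = fit_dmm(X, 1, FitConfig(seed=1))
        rep = recovery_report(truth, fit)
        assert rep["mean_l1_errors"][0] <= 0.03
        assert rep["theta_relative_errors"][0] <= 0.25

    def test_k2_assignment_recovery(self):
        """Well-separated two-component benchmark: >= 95% assignment accuracy."""
        spec = k2_benchmark_spec(seed=7)
        X, truth = sample_dataset(spec)
        fit = fit_dmm(X, 2, FitConfig(seed=1))
        rep = recovery_report(truth, fit)
        assert rep["assignment_accuracy"] >= 0.95

    def test_seeded_determinism(self, toy_counts):
        cfg = FitConfig(seed=9)
        f1 = fit_dmm(toy_counts, 2, cfg)
        f2 = fit_dmm(toy_counts, 2, cfg)
        assert len(f1.lower_bound_trace) == len(f2.lower_bound_trace)
        assert f1.neg_log_posterior == pytest.approx(f2.neg_log_posterior, abs=1e-12)

    def test_label_permutation_equivalence(self):
        """Random-soft inits that differ only by component relabelling give the same objective."""
        spec = k2_benchmark_spec(seed=3)
        X, _ = sample_dataset(spec)
        f1 = fit_dmm(X, 2, FitConfig(seed=4))
        perm_means_1 = sorted(np.round(c.mean[0], 4) for c in f1.model.components)
        f2 = fit_dmm(X, 2, FitConfig(seed=8, init_method="random_soft"))
        perm_means_2 = sorted(np.round(c.mean[0], 4) for c in f2.model.components)
        assert f1.neg_log_posterior == pytest.approx(f2.neg_log_posterior, rel=1e-4)
        np.testing.assert_allclose(perm_means_1, perm_means_2, atol=1e-3)

    def test_all_zero_taxon_column_stays_finite(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, size=(20, 4))
        counts[:, 2] = 0  # never-observed taxon
        X = CountMatrix(counts=counts)
        fit = fit_dmm(X, 1, FitConfig(seed=0))
        alpha = fit.model.components[0].alpha
        assert np.all(np.isfinite(alpha)) and np.all(alpha > 0)
        # pulled toward the Gamma prior's small-alpha region, far below observed taxa
        assert alpha[2] < alpha[[0, 1, 3]].min()

    def test_k_greater_than_n_warns(self):
        X = CountMatrix(counts=np.array([[3, 2], [1, 4]]))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("always")
            with pytest.warns(UserWarning, match="exceeds"):
                fit_dmm(X, 3, FitConfig(seed=0, max_em_iters=5))
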