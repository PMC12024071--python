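import numpy as np
import pytest
from scipy.stats import multivariate_normal

import misim as mi
from misim.cfa_ml_core import deviance_from_f, start_values


def brute_force_deviance(dataset, groups_params):
    """-2 log-likelihood by direct multivariate-normal density evaluation."""
    dev = 0.0
    for g, y in ((0, dataset.group1), (1, dataset.group2)):
        mu, sigma = mi.implied_moments(groups_params[g])
        dev += -2.0 * multivariate_normal.logpdf(y, mean=mu, cov=sigma).sum()
    return dev


class TestSampleMoments:
    def test_divisor_n_and_constant_column(self):
        g = np.array([[0.0, 1.0], [2.0, 1.0]])
        ds = mi.TwoGroupDataset(group1=g, group2=g + 1)
        m = mi.sample_moments(ds)
        assert m.means[0][0] == pytest.approx(1.0)
        assert m.covs[0][0, 0] == pytest.approx(1.0)  # divisor n, not n-1
        assert np.allclose(m.covs[0][1, :], 0.0)  # constant item

    def test_rejects_single_observation(self):
        ds = mi.TwoGroupDataset(group1=np.zeros((1, 2)), group2=np.zeros((5, 2)))
        with pytest.raises(ValueError):
            mi.sample_moments(ds)

    def test_large_sample_moments_near_population(self):
        spec = mi.make_population(50_000, 2.0, 0.8)
        m = mi.sample_moments(mi.generate_dataset(spec, 8))
        pars = spec.group_params(1)
        mu, sigma = mi.implied_moments(pars)
        assert np.abs(m.means[1] - mu).max() < 0.03
        assert np.abs(m.covs[1] - sigma).max() < 0.06


class TestImpliedMoments:
    def test_homogeneous_standardized_solution(self):
        pars = {"lam": np.full(12, 0.7), "nu": np.zeros(12),
                "psi": np.full(12, 0.51), "kappa": 0.0, "phi": 1.0}
        mu, sigma = mi.implied_moments(pars)
        assert np.allclose(mu, 0.0)
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.allclose(sigma[~np.eye(12, dtype=bool)], 0.49)

    def test_mean_structure(self):
        pars = {"lam": np.full(12, 0.7), "nu": np.zeros(12),
                "psi": np.full(12, 0.51), "kappa": 0.8, "phi": 1.0}
        mu, _ = mi.implied_moments(pars)
        assert np.allclose(mu, 0.56)

    def test_baseline_covariance_is_diagonal(self):
        spec = mi.ModelSpec("baseline")
        x = np.zeros(spec.n_free)
        pars = spec.unpack(x)[0]
        _, sigma = mi.implied_moments(pars)
        assert np.allclose(sigma, np.diag(np.diag(sigma)))

    def test_missing_parameter_is_named(self):
        with pytest.raises(ValueError, match="psi"):
            mi.implied_moments({"lam": np.ones(3), "nu": np.zeros(3),
                                "kappa": 0.0, "phi": 1.0})


class TestConfiguralReparam:
    def test_heterogeneous_group_maps_to_large_loading(self):
        lam_con, nu_con = mi.configural_reparam(0.7, 0.0, 0.8, 4.0)
        assert lam_con == pytest.approx(1.4)
        assert nu_con == pytest.approx(0.56)

    def test_identity_for_standardized_factor(self):
        lam_con, nu_con = mi.configural_reparam(0.7, -0.15, 0.0, 1.0)
        assert lam_con == pytest.approx(0.7)
        assert nu_con == pytest.approx(-0.15)
        _, nu2 = mi.configural_reparam(0.7, -0.15, 0.8, 1.0)
        assert nu2 == pytest.approx(0.41)

    def test_reparam_matches_large_sample_configural_fit(self):
        spec = mi.make_population(50_000, 4.0, 0.8)
        m = mi.sample_moments(mi.generate_dataset(spec, 12))
        fit = mi.fit_ml(mi.ModelSpec("configural"), m)
        g2 = fit.params[1]
        lam_con, nu_con = mi.configural_reparam(0.7, 0.0, 0.8, 4.0)
        assert np.abs(g2["lam"] - lam_con).max() < 0.03
        assert np.abs(g2["nu"] - nu_con).max() < 0.03

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            mi.configural_reparam(0.7, 0.0, 0.0, -1.0)


class TestDiscrepancy:
    def test_saturated_moments_give_zero(self):
        # when the sample moments equal the implied moments exactly, F = 0
        spec = mi.ModelSpec("configural")
        x = start_values(
            spec, mi.sample_moments(
                mi.generate_dataset(mi.make_population(50, 1.0, 0.0), 1)))
        groups = spec.unpack(x)
        implied = [mi.implied_moments(g) for g in groups]
        m = mi.SampleMoments(
            means=(implied[0][0], implied[1][0]),
            covs=(implied[0][1], implied[1][1]), sizes=(50, 50))
        assert mi.fml(spec.pack(groups), m, spec) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_model_pays_log_determinant_penalty(self, invariant_moments):
        # baseline at its closed-form optimum: mean and variance terms
        # vanish, leaving only the penalty for ignoring the correlations
        m = invariant_moments
        fit = mi.fit_ml(mi.ModelSpec("baseline"), m)
        expected = 0.0
        for g in (0, 1):
            w = m.sizes[g] / m.n_total
            s = m.covs[g]
            expected += w * (np.log(np.diag(s)).sum() - np.linalg.slogdet(s)[1])
        assert fit.f_ml == pytest.approx(expected, abs=1e-10)

    def test_mean_only_mismatch_is_mahalanobis(self, invariant_moments):
        m = invariant_moments
        spec = mi.ModelSpec("configural")
        fit = mi.fit_ml(spec, m)
        x = fit.x.copy()
        # shift group-1 intercepts: covariance part of F stays at optimum
        f0 = mi.fml(x, m, spec)
        shift = np.zeros(12)
        shift[0] = 0.3
        groups = fit.params
        mu, sigma = mi.implied_moments(groups[0])
        d = m.means[0] - (mu + shift)
        extra = (m.sizes[0] / m.n_total) * (
            d @ np.linalg.solve(sigma, d)
            - (m.means[0] - mu) @ np.linalg.solve(sigma, m.means[0] - mu))
        slot = [s for s in spec.slots if s.name == "nu" and s.group == 0][0]
        x[slot.start:slot.stop] += shift
        assert mi.fml(x, m, spec) - f0 == pytest.approx(extra, abs=1e-10)

    def test_t_equals_saturated_deviance_difference(self, toy_dataset):
        """Likelihood oracle: N*F must equal D(theta) - D(saturated)."""
        m = mi.sample_moments(toy_dataset)
        spec = mi.ModelSpec("configural", n_items=3)
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = start_values(spec, m) + 0.2 * rng.standard_normal(spec.n_free)
            f = mi.fml(x, m, spec)
            t = m.n_total * f
            dev = brute_force_deviance(toy_dataset, spec.unpack(x))
            assert t == pytest.approx(dev - m.saturated_deviance(), abs=1e-8)
            assert deviance_from_f(f, m) == pytest.approx(dev, abs=1e-8)

    def test_gradient_matches_finite_differences(self, invariant_moments):
        spec = mi.ModelSpec("scalar")
        x = start_values(spec, invariant_moments)
        rng = np.random.default_rng(3)
        x = x + 0.1 * rng.standard_normal(x.shape)
        f, grad = mi.fml(x, invariant_moments, spec, with_grad=True)
        eps = 1e-6
        for j in rng.choice(spec.n_free, size=10, replace=False):
            e = np.zeros_like(x)
            e[j] = eps
            fd = (mi.fml(x + e, invariant_moments, spec)
                  - mi.fml(x - e, invariant_moments, spec)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestModelDf:
    def test_free_parameter_counts_by_brute_force(self):
        expected_k = {"configural": 72, "metric": 61, "scalar": 50, "baseline": 48}
        expected_df = {"configural": 108, "metric": 119, "scalar": 130,
                       "baseline": 132}
        for level, k in expected_k.items():
            spec = mi.ModelSpec(level)
            table = spec.parameter_table()
            counted = sum(1 for row in table if row["status"] == "free")
            assert counted == k == spec.n_free
            assert mi.model_df(spec) == 180 - k == expected_df[level]

    def test_adjacent_df_gaps_are_11(self):
        dfs = [mi.model_df(mi.ModelSpec(lv))
               for lv in ("configural", "metric", "scalar")]
        assert np.diff(dfs).tolist() == [11, 11]


class TestFitML:
    def test_configural_parameter_recovery(self):
        """lam=0.7 and psi=0.51 recovered within 3 Monte Carlo SEs."""
        spec = mi.make_population(600, 1.0, 0.0)
        lam_hat, psi_hat = [], []
        for rep in range(40):
            m = mi.sample_moments(
                mi.generate_dataset(spec, mi.replication_seed(100, 0, rep)))
            fit = mi.fit_ml(mi.ModelSpec("configural"), m)
            assert fit.converged
            lam_hat.append(fit.params[0]["lam"].mean())
            psi_hat.append(fit.params[0]["psi"].mean())
        for est, truth in ((lam_hat, 0.7), (psi_hat, 0.51)):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * se + 1e-3

    def test_metric_recovers_latent_variance_ratio(self):
        spec = mi.make_population(600, 4.0, 0.0)
        phi2 = []
        for rep in range(30):
            m = mi.sample_moments(
                mi.generate_dataset(spec, mi.replication_seed(101, 0, rep)))
            phi2.append(mi.fit_ml(mi.ModelSpec("metric"), m).params[1]["phi"])
        phi2 = np.asarray(phi2)
        se = phi2.std(ddof=1) / np.sqrt(len(phi2))
        assert abs(phi2.mean() - 4.0) < 3 * se + 0.01

    def test_scalar_recovers_latent_mean_difference(self):
        spec = mi.make_population(600, 1.0, 0.8)
        kappa2 = []
        for rep in range(30):
            m = mi.sample_moments(
                mi.generate_dataset(spec, mi.replication_seed(102, 0, rep)))
            kappa2.append(mi.fit_ml(mi.ModelSpec("scalar"), m).params[1]["kappa"])
        kappa2 = np.asarray(kappa2)
        se = kappa2.std(ddof=1) / np.sqrt(len(kappa2))
        assert abs(kappa2.mean() - 0.8) < 3 * se + 0.01

    def test_nested_discrepancies_monotone(self):
        for seed in (1, 2, 3):
            spec = mi.make_population(150, 2.0, 0.8, 4, 0.25, "intercept")
            m = mi.sample_moments(mi.generate_dataset(spec, seed))
            f = {lv: mi.fit_ml(mi.ModelSpec(lv), m).f_ml
                 for lv in ("configural", "metric", "scalar")}
            assert f["scalar"] >= f["metric"] - 1e-9
            assert f["metric"] >= f["configural"] - 1e-9

    def test_invariant_to_observation_order(self, invariant_dataset):
        rng = np.random.default_rng(0)
        perm = rng.permutation(invariant_dataset.group1.shape[0])
        shuffled = mi.TwoGroupDataset(
            group1=invariant_dataset.group1[perm],
            group2=invariant_dataset.group2[perm])
        f1 = mi.fit_ml(mi.ModelSpec("metric"), mi.sample_moments(invariant_dataset))
        f2 = mi.fit_ml(mi.ModelSpec("metric"), mi.sample_moments(shuffled))
        assert f1.f_ml == pytest.approx(f2.f_ml, abs=1e-10)

    def test_t_scale_switch(self, invariant_moments):
        fn = mi.fit_ml(mi.ModelSpec("metric"), invariant_moments, t_scale="N")
        fn1 = mi.fit_ml(mi.ModelSpec("metric"), invariant_moments, t_scale="N-1")
        n = invariant_moments.n_total
        assert fn1.t_stat == pytest.approx(fn.t_stat * (n - 1) / n, rel=1e-9)

    def test_baseline_closed_form_is_optimal(self, invariant_moments):
        fit = mi.fit_ml(mi.ModelSpec("baseline"), invariant_moments)
        spec = mi.ModelSpec("baseline")
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = fit.x + 0.05 * rng.standard_normal(spec.n_free)
            assert mi.fml(x, invariant_moments, spec) >= fit.f_ml
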