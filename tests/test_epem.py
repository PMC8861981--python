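"""Entropy-penalized EM: log-density oracle, ascent, recovery, assignment."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from dimorph import (EPEMConfig, SimConfig, TemporalMixture, assign_labels,
                     fit_epem, profile_loglik, simulate_profile_mixture)
from dimorph.io import ValidationError
from dimorph.profiles import ProfileSet, design_matrices

AGES = (3.0, 6.0, 9.0, 12.0, 18.0)


def random_params(rng):
    X, Z = design_matrices(AGES)
    beta = rng.normal(size=4)
    A = rng.normal(size=(3, 3))
    D = A @ A.T / 3.0
    sigma2 = float(rng.uniform(0.02, 2.0))
    return X, Z, beta, D, sigma2


class TestProfileLoglik:
    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(314)
        for _ in range(100):
            X, Z, beta, D, sigma2 = random_params(rng)
            y = rng.normal(size=5)
            ours = profile_loglik(y, beta, D, sigma2, X, Z)
            V = Z @ D @ Z.T + sigma2 * np.eye(5)
            oracle = stats.multivariate_normal(mean=X @ beta, cov=V).logpdf(y)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_zero_random_effects_is_independent_normals(self):
        rng = np.random.default_rng(9)
        X, Z, beta, _, sigma2 = random_params(rng)
        y = rng.normal(size=5)
        ours = profile_loglik(y, beta, np.zeros((3, 3)), sigma2, X, Z)
        expected = stats.norm(loc=X @ beta, scale=np.sqrt(sigma2)).logpdf(y).sum()
        assert ours == pytest.approx(expected, abs=1e-10)

    def test_density_decreases_beyond_mode_in_sigma2(self):
        """At y = X beta the log-density falls monotonically as sigma2 grows
        (flat-density limit)."""
        X, Z, beta, D, _ = random_params(np.random.default_rng(2))
        y = X @ beta
        vals = [profile_loglik(y, beta, np.zeros((3, 3)), s2, X, Z)
                for s2 in np.logspace(-2, 3, 30)]
        assert np.all(np.diff(vals) < 0)


def _random_profiles(rng, n=60):
    vals = rng.normal(size=(n, 5))
    ids = [(f"p{i}", "M") for i in range(n)]
    return ProfileSet(ids, AGES, vals, standardized=True)


class TestFitting:
    def test_objective_ascent_fixed_lambda(self):
        """Penalized objective is non-decreasing every iteration for fixed
        lambda, across seeded random datasets."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = _random_profiles(rng)
            cfg = EPEMConfig(k_max=4, lambda_penalty=0.3, anneal=False,
                             n_restarts=1, max_iter=60, seed=seed)
            model, _ = fit_epem(prof, cfg)
            trace = np.asarray(model.objective_trace)
            assert np.all(np.diff(trace) >= -1e-8), f"seed {seed}"

    def test_two_separated_curves_recovered_exactly(self):
        rng = np.random.default_rng(11)
        X, Z = design_matrices(AGES)
        s = X[:, 1]
        up = (s - s.mean()) / s.std(ddof=1)
        curves = np.array([up, -up])
        labels_true = np.repeat([0, 1], 100)
        vals = curves[labels_true] + rng.normal(0, 0.1, size=(200, 5))
        prof = ProfileSet([(f"p{i}", "M") for i in range(200)], AGES, vals,
                          standardized=True)
        model, assign = fit_epem(prof, EPEMConfig(k_max=6, n_restarts=3, seed=4))
        assert model.K == 2
        assert adjusted_rand_score(labels_true, assign.labels) == 1.0

    def test_identical_profiles_collapse_to_one_cluster(self):
        X, _ = design_matrices(AGES)
        curve = X @ np.array([0.1, 0.8, -0.3, 0.2])  # exactly cubic
        vals = np.tile(curve, (30, 1))
        prof = ProfileSet([(f"p{i}", "M") for i in range(30)], AGES, vals,
                          standardized=True)
        cfg = EPEMConfig(k_max=4, n_restarts=2, seed=0, variance_floor=1e-6)
        model, assign = fit_epem(prof, cfg)
        assert model.K == 1
        assert model.sigma2 == pytest.approx(1e-6, rel=1e-6)
        assert np.all(assign.labels == 1)

    def test_object_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        prof, _ = simulate_profile_mixture(150, SimConfig(K_true=3, seed=21))
        cfg = EPEMConfig(k_max=5, n_restarts=2, seed=3)
        model1, assign1 = fit_epem(prof, cfg)
        perm = rng.permutation(prof.n_objects)
        prof_p = ProfileSet([prof.object_ids[i] for i in perm], prof.age_grid,
                            prof.values[perm], standardized=True)
        model2 = TemporalMixture(prof_p, config=cfg).fit().cluster_model
        # the canonical relabeling makes the fitted model order-invariant
        assert model2.K == model1.K
        np.testing.assert_allclose(model2.beta, model1.beta, atol=1e-4)
        np.testing.assert_allclose(model2.pi, model1.pi, atol=1e-4)

    def test_parameter_recovery_on_model_data(self):
        """beta recovered within RMSE 0.1 per coefficient, K = K_true,
        on data simulated from the model itself (majority of seeds)."""
        hits = 0
        for seed in range(5):
            cfg_sim = SimConfig(K_true=4, sigma2_true=0.05, seed=seed)
            prof, labels = simulate_profile_mixture(2000, cfg_sim)
            res = TemporalMixture(prof, k_max=10, n_restarts=3,
                                  seed=seed + 50).fit()
            if res.K != 4:
                continue
            # align fitted clusters to truth by mean-curve distance
            X, _ = design_matrices(AGES)
            true_curves = cfg_sim.beta_true @ X.T
            fit_curves = res.cluster_model.mean_curves()
            rmse_ok = True
            for k in range(4):
                j = np.argmin(((true_curves - fit_curves[k]) ** 2).sum(axis=1))
                rmse = np.sqrt(np.mean(
                    (res.cluster_model.beta[k] - cfg_sim.beta_true[j]) ** 2))
                rmse_ok &= rmse < 0.1
            if rmse_ok and adjusted_rand_score(labels,
                                               res.assignments.labels) >= 0.9:
                hits += 1
        assert hits >= 4

    def test_unpenalized_limit_is_plain_em(self):
        """With lambda=0 the weight update is the ordinary EM n_k/N and the
        final objective equals the independently computed log-likelihood."""
        prof, _ = simulate_profile_mixture(120, SimConfig(K_true=2, seed=8))
        cfg = EPEMConfig(k_max=2, lambda_penalty=0.0, anneal=False,
                         n_restarts=1, max_iter=80, seed=8)
        model, assign = fit_epem(prof, cfg)
        ll = np.array([[profile_loglik(y, model.beta[k], model.D[k],
                                       model.sigma2, model.X, model.Z)
                        for k in range(model.K)] for y in prof.values])
        from scipy.special import logsumexp
        obj = float(logsumexp(ll + np.log(model.pi), axis=1).sum())
        assert model.objective_trace[-1] == pytest.approx(obj, abs=1e-6)
        # EM fixed point: pi equals average responsibility
        np.testing.assert_allclose(model.pi,
                                   assign.responsibilities.mean(axis=0),
                                   atol=1e-4)

    def test_too_few_objects_rejected(self):
        prof = _random_profiles(np.random.default_rng(0), n=5)
        with pytest.raises(ValidationError, match="k_max"):
            TemporalMixture(prof, k_max=10)

    def test_unstandardized_rejected(self, rng):
        prof = ProfileSet([("a", "M"), ("b", "M")], AGES,
                          rng.normal(size=(2, 5)), standardized=False)
        with pytest.raises(ValidationError, match="standardized"):
            TemporalMixture(prof, k_max=2)


class TestAssignment:
    def test_on_curve_profile_gets_confident_label(self):
        prof, _ = simulate_profile_mixture(200, SimConfig(K_true=2, seed=5))
        model, _ = fit_epem(prof, EPEMConfig(k_max=4, n_restarts=2, seed=5))
        # a profile exactly on cluster 1's mean curve
        on_curve = model.mean_curves()[0]
        test_prof = ProfileSet([("probe", "M")], AGES, on_curve[None, :],
                               standardized=True)
        assign = assign_labels(model, test_prof)
        assert assign.labels[0] == 1
        assert assign.responsibilities[0, 0] > 0.999

    def test_degenerate_pi_assigns_everything_to_one(self):
        prof, _ = simulate_profile_mixture(50, SimConfig(K_true=2, seed=6))
        model, _ = fit_epem(prof, EPEMConfig(k_max=2, n_restarts=1, seed=6))
        model.pi = np.array([1.0, 0.0])
        assign = assign_labels(model, prof)
        assert np.all(assign.labels == 1)

    def test_responsibilities_normalized(self):
        prof, _ = simulate_profile_mixture(80, SimConfig(K_true=3, seed=7))
        model, assign = fit_epem(prof, EPEMConfig(k_max=5, n_restarts=1, seed=7))
        np.testing.assert_allclose(assign.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(
            assign.labels, np.argmax(assign.responsibilities, axis=1) + 1)


def test_model_json_roundtrip(tmp_path):
    prof, _ = simulate_profile_mixture(60, SimConfig(K_true=2, seed=1))
    model, _ = fit_epem(prof, EPEMConfig(k_max=3, n_restarts=1, seed=1))
    path = tmp_path / "model.json"
    model.to_json(path)
    from dimorph.epem import ClusterModel
    back = ClusterModel.from_json(path)
    assert back.K == model.K
    np.testing.assert_allclose(back.beta, model.beta, atol=1e-12)
    np.testing.assert_allclose(back.pi, model.pi, atol=1e-12)
    np.testing.assert_allclose(back.D, model.D, atol=1e-12)
    assert back.sigma2 == pytest.approx(model.sigma2)
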