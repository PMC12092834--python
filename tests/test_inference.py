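"""Amortized posterior estimation: toy-oracle accuracy and analysis toolkit."""

import numpy as np
import pytest

from mea_sbi.fixtures import toy_posterior_moments, toy_training_set
from mea_sbi.inference import (
    Posterior,
    PosteriorModel,
    build_training_set,
    conditional_corr_matrix,
    conditional_posterior,
    load_model,
    parameter_recovery_error,
    posterior_for,
    posterior_mode,
    ppc_check,
    save_model,
    sensitivity_scores,
    train_nde,
)
from mea_sbi.nde import ConditionalGaussianMixture


@pytest.fixture(scope="module")
def toy_model(toy_ts):
    return train_nde(toy_ts, seed=0, min_n=100)


def _gaussian_model(mean, cov, names=None) -> PosteriorModel:
    """Hand-built model whose posterior is one Gaussian, independent of x."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    d = len(mean)
    cde = ConditionalGaussianMixture.__new__(ConditionalGaussianMixture)
    cde.d_theta = d
    cde.weights_ = np.array([1.0])
    joint = np.zeros((d + 1, d + 1))
    joint[:d, :d] = cov
    joint[d, d] = 1.0  # one dummy feature, uncoupled
    cde.means_ = np.concatenate([mean, [0.0]])[None, :]
    cde.covs_ = joint[None, :, :]
    names = names or tuple(f"p{i}" for i in range(d))
    return PosteriorModel(
        cde, tuple(names), ("f0",), np.zeros(d), np.ones(d),
        np.zeros(1), np.ones(1), np.zeros(d), np.ones(d),
    )


class TestTrainingSet:
    def test_shapes_and_alignment(self, toy_ts):
        assert toy_ts.theta.shape == (5000, 1) and toy_ts.x.shape == (5000, 1)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_training_set(
                [np.zeros(1)] * 3, np.zeros((2, 1)),
                param_names=("a",), prior_low=np.zeros(1), prior_high=np.ones(1),
                feature_names=("f",),
            )

    def test_min_n_enforced(self, toy_ts):
        small = toy_training_set(n=50, seed=0)
        with pytest.raises(ValueError, match="minimum"):
            train_nde(small, min_n=500)

    def test_constant_feature_column_named_in_error(self, toy_ts):
        bad = toy_training_set(n=600, seed=1)
        bad.x[:, 0] = 2.5
        with pytest.raises(ValueError, match="x_0"):
            train_nde(bad, min_n=100)


class TestToyPosterior:
    """Linear-Gaussian simulator x = theta + N(0, 0.1^2), uniform prior on [0,1]:
    the analytic posterior is the truncated Gaussian N(x_o, 0.1^2)."""

    def test_posterior_mean_and_sd_match_analytic(self, toy_model):
        post = posterior_for(np.array([0.5]), toy_model)
        s = post.sample(2000, seed=1)
        m_true, sd_true = toy_posterior_moments(0.5)
        assert abs(s.mean() - m_true) < 0.03
        assert abs(s.std() - sd_true) / sd_true < 0.30

    def test_mode_matches_analytic_map(self, toy_model):
        post = posterior_for(np.array([0.5]), toy_model)
        mode = posterior_mode(post, seed=2)
        assert abs(mode[0] - 0.5) < 0.03

    def test_two_observations_one_model_distinct_posteriors(self, toy_model):
        pa = posterior_for(np.array([0.25]), toy_model)
        pb = posterior_for(np.array([0.75]), toy_model)
        assert pb.sample(500, 3).mean() - pa.sample(500, 3).mean() > 0.3

    def test_amortized_no_retraining_on_evaluation(self, toy_model, monkeypatch):
        def _boom(*a, **k):
            raise AssertionError("fit() must not run at evaluation time")

        monkeypatch.setattr(ConditionalGaussianMixture, "fit", _boom)
        post = posterior_for(np.array([0.4]), toy_model)
        post.sample(10, 0)
        post.log_prob(np.array([[0.4]]))

    def test_training_deterministic_given_seed(self, toy_ts):
        m1 = train_nde(toy_ts, seed=5, min_n=100)
        m2 = train_nde(toy_ts, seed=5, min_n=100)
        probe = np.linspace(0.05, 0.95, 10)[:, None]
        p1 = posterior_for(np.array([0.5]), m1).log_prob(probe)
        p2 = posterior_for(np.array([0.5]), m2).log_prob(probe)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_samples_respect_prior_box(self, toy_model):
        s = posterior_for(np.array([0.02]), toy_model).sample(2000, 4)
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_out_of_range_observation_warns_not_fails(self, toy_model):
        with pytest.warns(UserWarning, match="training sd"):
            posterior_for(np.array([50.0]), toy_model)

    def test_simulation_based_calibration_ranks_uniform(self, toy_model):
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ranks = []
        for _ in range(100):
            th = rng.uniform()
            x = th + rng.normal(0, 0.1)
            s = posterior_for(np.array([x]), toy_model).sample(99, rng)[:, 0]
            ranks.append(np.sum(s < th))
        u = (np.array(ranks) + 0.5) / 100
        assert kstest(u, "uniform").pvalue > 0.01


class TestConditionals:
    def test_independent_posterior_conditional_equals_marginal(self):
        model = _gaussian_model([0.5, 0.5], np.diag([0.01, 0.02]))
        post = Posterior(model, np.zeros(1))
        cd = conditional_posterior(post, np.array([0.5, 0.7]), (0,), grid_n=200)
        # conditioning on an independent coordinate leaves the marginal intact
        assert cd.mean()[0] == pytest.approx(0.5, abs=0.005)
        assert cd.sd()[0] == pytest.approx(0.1, abs=0.005)

    def test_correlated_gaussian_narrows_by_sqrt_one_minus_rho2(self):
        rho, sd = 0.9, 0.08
        cov = sd**2 * np.array([[1, rho], [rho, 1]])
        model = _gaussian_model([0.5, 0.5], cov)
        post = Posterior(model, np.zeros(1))
        cd = conditional_posterior(post, np.array([0.5, 0.5]), (0,), grid_n=400)
        expected = sd * np.sqrt(1 - rho**2)
        assert cd.sd()[0] == pytest.approx(expected, rel=0.05)

    def test_no_free_parameters_rejected(self):
        model = _gaussian_model([0.5, 0.5], np.diag([0.01, 0.01]))
        post = Posterior(model, np.zeros(1))
        with pytest.raises(ValueError):
            conditional_posterior(post, np.array([0.5, 0.5]), ())

    def test_corr_matrix_detects_sum_constraint(self):
        # theta_0 + theta_1 ~ const: conditional correlation -> -1
        sd = 0.1
        cov = sd**2 * np.array([[1, -0.995], [-0.995, 1]])
        model = _gaussian_model([0.5, 0.5], cov)
        post = Posterior(model, np.zeros(1))
        ccm = conditional_corr_matrix(post, n_conditionals=20, n_points=50, seed=0)
        assert ccm.mean_r[0, 1] < -0.9
        assert np.all(np.diag(ccm.mean_r) == 1.0)
        assert ccm.p_values[0, 1] < 1e-6

    def test_corr_matrix_null_for_independent_posterior(self):
        model = _gaussian_model([0.5, 0.5], np.diag([0.01, 0.01]))
        post = Posterior(model, np.zeros(1))
        ccm = conditional_corr_matrix(post, n_conditionals=20, n_points=50, seed=1)
        assert abs(ccm.mean_r[0, 1]) < 0.12
        assert ccm.p_values[0, 1] > 0.01


class TestSensitivity:
    def test_narrow_dimension_scores_highest(self):
        model = _gaussian_model([0.5, 0.5, 0.5], np.diag([0.0001, 0.01, 0.01]))
        post = Posterior(model, np.zeros(1))
        scores = sensitivity_scores(post, n_samples=400, seed=0)
        assert np.argmax(scores) == 0 and scores[0] == 1.0

    def test_isotropic_gaussian_scores_nearly_equal(self):
        model = _gaussian_model([0.5] * 3, np.eye(3) * 0.01)
        post = Posterior(model, np.zeros(1))
        scores = sensitivity_scores(post, n_samples=800, seed=1)
        assert scores.min() > 0.8 * scores.max()


class TestPpcAndPre:
    def test_centered_posterior_passes_all_marginals(self):
        theta_star = np.array([0.4, 0.6])
        model = _gaussian_model(theta_star, np.diag([0.003, 0.003]))
        res = ppc_check(model, theta_star, x_obs=np.zeros(1), seed=0)
        assert res["pass"] and all(res["univariate"].values())

    def test_opposite_corner_posterior_fails(self):
        model = _gaussian_model([0.9, 0.9], np.diag([0.001, 0.001]))
        res = ppc_check(model, np.array([0.1, 0.1]), x_obs=np.zeros(1), seed=0)
        assert not res["pass"]

    def test_toy_ground_truth_passes(self, toy_model):
        res = ppc_check(toy_model, np.array([0.5]), x_obs=np.array([0.5]), seed=0)
        assert res["pass"]

    def test_pre_zero_when_samples_equal_truth(self):
        class _Stub:
            class model:
                prior_low = np.zeros(2)
                prior_high = np.ones(2)

            def sample(self, n, seed):
                return np.tile([0.3, 0.7], (n, 1))

        pre = parameter_recovery_error(_Stub(), np.array([0.3, 0.7]), n=500)
        np.testing.assert_allclose(pre, 0.0)

    def test_pre_quarter_for_uniform_marginal_midpoint_truth(self):
        class _Stub:
            class model:
                prior_low = np.zeros(1)
                prior_high = np.ones(1)

            def sample(self, n, seed):
                return np.random.default_rng(0).uniform(size=(n, 1))

        pre = parameter_recovery_error(_Stub(), np.array([0.5]), n=20_000)
        assert pre[0] == pytest.approx(0.25, abs=0.01)

    def test_pre_half_for_uniform_marginal_edge_truth(self):
        class _Stub:
            class model:
                prior_low = np.zeros(1)
                prior_high = np.ones(1)

            def sample(self, n, seed):
                return np.random.default_rng(1).uniform(size=(n, 1))

        pre = parameter_recovery_error(_Stub(), np.array([0.0]), n=20_000)
        assert pre[0] == pytest.approx(0.5, abs=0.01)


class TestSerialization:
    def test_model_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(toy_model, path)
        loaded = load_model(path)
        probe = np.linspace(0.1, 0.9, 7)[:, None]
        p0 = posterior_for(np.array([0.5]), toy_model).log_prob(probe)
        p1 = posterior_for(np.array([0.5]), loaded).log_prob(probe)
        np.testing.assert_allclose(p0, p1, rtol=1e-12)
        assert loaded.param_names == toy_model.param_names
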