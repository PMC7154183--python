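"""Design coding, log joint density, and the Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import quailfcm as q
from quailfcm.exceptions import SchemaError
from quailfcm.model import EFFECT_NAMES

from helpers import batch_means_se, brute_force_log_joint, random_walk_metropolis


def _tiny_table():
    """Two birds, a handful of windows across all treatments."""
    rows = []
    for bird, w_g in [("a", 160.0), ("b", 190.0)]:
        for trt in ("reference", "acth", "biological"):
            for w in (0, 1, 5, 11):
                rows.append((bird, "adult", "male", w_g, trt, w,
                             0.0, 9, w == 5, 10.0 + w))
    return pd.DataFrame(rows, columns=q.cohort.SAMPLE_COLUMNS)


class TestBuildDesign:
    def test_baseline_row_coding(self):
        t = _tiny_table()
        data = q.build_design(t)
        assert data.effect_names == EFFECT_NAMES
        # reference, window 0, day rows: only intercept and weight active
        i = np.where((t["treatment"] == "reference") & (t["window_index"] == 0)
                     & (t["bird_id"] == "a"))[0][0]
        row = data.X[i]
        np.testing.assert_allclose(row[:7], [1, 0, 0, 0, 0, 0, 0])
        # two birds at 160/190 g -> z-scores are -/+ 1/sqrt(2)... with ddof=1: -0.707
        assert row[7] == pytest.approx(-np.sqrt(0.5))

    def test_acth_window_one_coding(self):
        t = _tiny_table()
        data = q.build_design(t)
        i = np.where((t["treatment"] == "acth") & (t["window_index"] == 1)
                     & (t["bird_id"] == "a"))[0][0]
        row = data.X[i]
        assert (row[1], row[3], row[4]) == (1.0, 1.0, 1.0)
        assert (row[2], row[5]) == (0.0, 0.0)

    def test_interactions_are_products_and_reference_all_ones(self, samples):
        data = q.build_design(samples)
        np.testing.assert_array_equal(data.X[:, 0], 1.0)
        np.testing.assert_allclose(data.X[:, 4], data.X[:, 1] * data.X[:, 3])
        np.testing.assert_allclose(data.X[:, 5], data.X[:, 2] * data.X[:, 3])
        assert set(np.unique(data.X[:, 1])) <= {0.0, 1.0}
        assert set(np.unique(data.X[:, 6])) <= {0.0, 1.0}

    def test_weight_column_standardized_over_birds(self, samples):
        data = q.build_design(samples)
        per_bird = pd.DataFrame({"b": data.bird_index, "w": data.X[:, 7]}) \
            .groupby("b")["w"].first()
        assert per_bird.mean() == pytest.approx(0.0, abs=1e-12)
        assert per_bird.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_published_coefficients_predict_return_to_baseline(self):
        # at the shipped truths, ACTH window 11 is back near the reference level
        truth = q.load_default_truth()["effects"]
        mu = {k: v["mu"] for k, v in truth.items()}
        lp = mu["Reference"] + mu["ACTH"] + 11 * mu["Time"] + 11 * mu["ACTH:Time"]
        assert lp == pytest.approx(16.47, abs=0.005)
        assert lp == pytest.approx(mu["Reference"], abs=0.5)

    def test_unknown_treatment_rejected(self):
        t = _tiny_table()
        t.loc[0, "treatment"] = "sham"
        with pytest.raises(SchemaError):
            q.build_design(t)

    def test_zero_weight_variance_warns_and_zeroes_column(self):
        t = _tiny_table()
        t["weight_g"] = 170.0
        with pytest.warns(UserWarning, match="weight"):
            data = q.build_design(t)
        np.testing.assert_array_equal(data.X[:, 7], 0.0)


def _toy_data(seed=0, n_birds=2, n_obs_per=4, K=8):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_birds * n_obs_per, K))
    X[:, 0] = 1.0
    y = rng.standard_normal(n_birds * n_obs_per) * 3 + 10
    idx = np.repeat(np.arange(n_birds), n_obs_per)
    return q.ModelData(y=y, X=X, bird_index=idx,
                       bird_ids=np.array([f"b{j}" for j in range(n_birds)]))


def _random_state(rng, J, K):
    return {"beta": rng.standard_normal((J, K)) * 2 + 5,
            "mu": rng.standard_normal(K) * 3,
            "tau": rng.gamma(2.0, 1.0),
            "tau_k": rng.gamma(2.0, 1.0, K)}


class TestLogJoint:
    def test_matches_brute_force_oracle(self):
        data = _toy_data()
        cfg = q.McmcConfig()
        rng = np.random.default_rng(1)
        for _ in range(3):
            state = _random_state(rng, data.n_birds, data.n_effects)
            assert q.log_joint(data, state, cfg) == pytest.approx(
                brute_force_log_joint(data, state, cfg), abs=1e-10)

    def test_translation_shifts_only_prior_terms(self):
        data = _toy_data()
        cfg = q.McmcConfig()
        rng = np.random.default_rng(2)
        state = _random_state(rng, data.n_birds, data.n_effects)
        c = 3.7
        shifted = {k: np.copy(v) if isinstance(v, np.ndarray) else v
                   for k, v in state.items()}
        data2 = q.ModelData(y=data.y + c, X=data.X, bird_index=data.bird_index,
                            bird_ids=data.bird_ids)
        shifted["beta"][:, 0] += c
        shifted["mu"][0] += c
        # likelihood and beta-prior terms unchanged (X[:,0]=1); only the
        # mu_Reference hyperprior moves, by the closed-form normal difference
        def mu_prior(m):
            return stats.norm.logpdf(m, 0, 1 / np.sqrt(cfg.prior_mu_precision))
        delta = mu_prior(shifted["mu"][0]) - mu_prior(state["mu"][0])
        assert q.log_joint(data2, shifted, cfg) - q.log_joint(data, state, cfg) \
            == pytest.approx(delta, abs=1e-8)

    def test_concave_in_each_beta_coordinate(self):
        data = _toy_data()
        cfg = q.McmcConfig()
        rng = np.random.default_rng(3)
        state = _random_state(rng, data.n_birds, data.n_effects)
        j, k = 1, 2
        # conditional mode of beta_{j,k} given everything else
        rows = data.bird_index == j
        Xj, yj = data.X[rows], data.y[rows]
        partial = yj - Xj @ state["beta"][j] + Xj[:, k] * state["beta"][j][k]
        tau, tau_k = state["tau"], state["tau_k"][k]
        mode = (tau * Xj[:, k] @ partial + tau_k * state["mu"][k]) \
            / (tau * Xj[:, k] @ Xj[:, k] + tau_k)
        vals = []
        for step in (0.0, 0.5, 1.0, 2.0):
            s = {kk: np.copy(v) if isinstance(v, np.ndarray) else v
                 for kk, v in state.items()}
            s["beta"][j, k] = mode + step
            vals.append(q.log_joint(data, s, cfg))
        assert vals == sorted(vals, reverse=True)

    def test_nonpositive_precision_rejected(self):
        data = _toy_data()
        state = _random_state(np.random.default_rng(4), 2, 8)
        state["tau"] = -1.0
        with pytest.raises(ValueError):
            q.log_joint(data, state, q.McmcConfig())


class TestGibbsSampler:
    def test_bitwise_determinism(self):
        data = _toy_data(seed=5, n_birds=3, n_obs_per=5)
        cfg = q.McmcConfig(n_chains=2, n_iter=200, n_burn=100, seed=31)
        d1, d2 = q.run_mcmc(data, cfg), q.run_mcmc(data, cfg)
        np.testing.assert_array_equal(d1.mu, d2.mu)
        np.testing.assert_array_equal(d1.tau, d2.tau)
        np.testing.assert_array_equal(d1.beta, d2.beta)

    def test_precisions_strictly_positive(self, small_fit):
        assert (small_fit.tau > 0).all()
        assert (small_fit.tau_k > 0).all()

    def test_single_bird_conjugate_closed_form(self):
        # one bird, intercept-only, precisions pinned by sharp gamma priors
        # and mu pinned at 0 by a huge prior precision: the beta posterior is
        # the standard precision-weighted normal combination
        rng = np.random.default_rng(6)
        n = 12
        y = rng.normal(4.0, 1.0, n)
        X = np.ones((n, 1))
        tau0 = 1.0
        big = 1e8
        est = q.HierarchicalGibbsRegressor(
            n_chains=2, n_iter=4000, n_burn=1000,
            prior_mu_precision=1e12,           # pins mu at ~0
            prior_gamma_shape=big, prior_gamma_rate=big,  # pins tau, tau_k at 1
            random_state=17)
        est.fit(X, y, groups=np.zeros(n, int))
        beta_draws = est.draws_.beta[:, :, 0, 0].ravel()
        expected_mean = tau0 * y.sum() / (tau0 * n + tau0)   # prior mean 0
        expected_sd = 1.0 / np.sqrt(tau0 * n + tau0)
        mc_se = beta_draws.std(ddof=1) / np.sqrt(200)  # generous ESS guess
        assert beta_draws.mean() == pytest.approx(expected_mean, abs=3 * mc_se)
        assert beta_draws.std(ddof=1) == pytest.approx(expected_sd, rel=0.1)

    def test_matches_metropolis_oracle_on_toy_instance(self):
        data = _toy_data(seed=7, n_birds=3, n_obs_per=10, K=2)
        cfg = q.McmcConfig(n_chains=2, n_iter=6000, n_burn=2000, seed=23)
        draws = q.run_mcmc(data, cfg)
        gibbs_mu = draws.pooled("mu")
        mh_mu, acc = random_walk_metropolis(data, cfg, n_steps=120_000, seed=99,
                                            scale=0.2)
        assert 0.1 < acc < 0.6
        for k in range(2):
            se = np.hypot(batch_means_se(mh_mu[:, k]),
                          batch_means_se(gibbs_mu[:, k]))
            assert gibbs_mu[:, k].mean() == pytest.approx(
                mh_mu[:, k].mean(), abs=3 * se + 1e-9)

    def test_shrinks_to_ols_when_individual_variation_vanishes(self):
        cfg = q.GeneratorConfig(seed=19, true_sigma_k=np.zeros(8),
                                residual_sd=2.0, defecation_prob=1.0)
        t = q.simulate_fcm(q.make_cohort(cfg), cfg)
        data = q.build_design(t)
        draws = q.run_mcmc(data, q.McmcConfig(n_chains=2, n_iter=2000,
                                              n_burn=1000, seed=3))
        ols = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        post = draws.pooled("mu").mean(axis=0)
        np.testing.assert_allclose(post, ols, atol=0.35)

    def test_log_joint_stationary_after_burn_in(self, samples):
        data = q.build_design(samples)
        est = q.HierarchicalGibbsRegressor(n_chains=1, n_iter=1500, n_burn=500,
                                           track_log_joint=True, random_state=8)
        est.fit(data.X, data.y, groups=data.bird_index)
        lj = est.draws_.log_joint[0]
        res = stats.linregress(np.arange(len(lj)), lj)
        t_stat = res.slope / res.stderr
        assert abs(t_stat) < 3.0

    def test_too_few_observations_rejected(self):
        data = _toy_data(n_birds=1, n_obs_per=4)   # N=4 <= K=8
        with pytest.raises(ValueError):
            q.run_mcmc(data, q.McmcConfig(n_iter=10, n_burn=5))

    def test_sklearn_params_round_trip(self):
        est = q.HierarchicalGibbsRegressor(n_iter=50, n_burn=10)
        params = est.get_params()
        clone = q.HierarchicalGibbsRegressor(**params)
        assert clone.get_params() == params
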