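"""The grid Bayesian filter: priors, steps, full runs, and its oracles."""
import math

import numpy as np
import pytest

from affectvar import (
    FilterConfig,
    GenerativeParams,
    GridDim,
    RatingSeries,
    init_posterior,
    kalman_reference,
    predict_step,
    run_filter,
    run_filter_batch,
    simulate_subject,
    update_step,
)
from affectvar.model import AffectFilter, _Kernels
from affectvar.exceptions import (
    ConfigurationError,
    ContractViolationError,
    DegenerateLikelihoodError,
    InsufficientDataError,
)
from conftest import make_series


def tiny_config(n=3):
    """A config with n points per dimension for oracle-sized problems."""
    return FilterConfig.default((0.0, 1.0), n_mu=n, n_log_vmu=n, n_log_sd=n, n_kmu=n, n_vsd=n)


def pinned_config(vmu, sd, n_mu=161, mu_range=(-0.5, 1.5)):
    """Volatility/noise/rates pinned: the filter's local-level (Kalman) limit."""
    return FilterConfig(
        mu=GridDim.linear(*mu_range, n_mu),
        log_vmu=GridDim.pinned(math.log(vmu)),
        log_sd=GridDim.pinned(math.log(sd)),
        kmu=GridDim.pinned(1e-9),
        vsd=GridDim.pinned(1e-9),
    )


class TestInitPosterior:
    def test_uniform_prior_mass_per_cell(self):
        cfg = tiny_config(3)
        post = init_posterior(cfg)
        assert np.allclose(post.joint, 1.0 / 3**5)
        assert abs(post.total_mass - 1.0) < 1e-10

    def test_pinned_dimension_is_point_mass(self):
        cfg = pinned_config(0.1, 0.1, n_mu=5)
        post = init_posterior(cfg)
        assert post.marginal("log_vmu").shape == (1,)
        assert post.marginal("log_vmu")[0] == pytest.approx(1.0)
        assert abs(post.total_mass - 1.0) < 1e-10

    def test_empty_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(
                mu=GridDim(points=np.array([]), prior=np.array([])),
                log_vmu=GridDim.pinned(0.0),
                log_sd=GridDim.pinned(0.0),
                kmu=GridDim.pinned(0.1),
                vsd=GridDim.pinned(0.1),
            )


class TestPredictStep:
    def test_no_dynamics_leaves_posterior_unchanged(self):
        cfg = pinned_config(1e-12, 0.1, n_mu=25, mu_range=(0.0, 1.0))
        post = update_step(predict_step(init_posterior(cfg)), 0.6)
        post2 = predict_step(post)
        assert np.allclose(post2.joint, post.joint, atol=1e-9)

    def test_gaussian_moment_spread(self):
        # point mass on mu=0.5 diffusing with vmu=0.1
        cfg = pinned_config(0.1, 0.1, n_mu=401, mu_range=(-1.5, 2.5))
        mu_prior = np.zeros(401)
        mu_prior[np.argmin(np.abs(cfg.mu.points - 0.5))] = 1.0
        cfg = FilterConfig(
            mu=GridDim(points=cfg.mu.points, prior=mu_prior),
            log_vmu=cfg.log_vmu,
            log_sd=cfg.log_sd,
            kmu=cfg.kmu,
            vsd=cfg.vsd,
        )
        post = predict_step(init_posterior(cfg))
        marg = post.marginal("mu")
        mean = marg @ cfg.mu.points
        sd = math.sqrt(marg @ (cfg.mu.points - mean) ** 2)
        assert mean == pytest.approx(0.5, abs=1e-6)
        assert sd == pytest.approx(0.1, rel=0.10)

    def test_entropy_of_mu_marginal_never_decreases(self):
        cfg = FilterConfig.default((0.0, 1.0), n_mu=15, n_log_vmu=5, n_log_sd=5, n_kmu=3, n_vsd=3)
        post = update_step(predict_step(init_posterior(cfg)), 0.5)

        def ent(p):
            m = p.marginal("mu")
            m = m[m > 0]
            return float(-(m * np.log(m)).sum())

        for _ in range(5):
            nxt = predict_step(post)
            assert ent(nxt) >= ent(post) - 1e-12
            post = nxt

    def test_non_normalized_input_rejected(self):
        cfg = tiny_config(3)
        post = init_posterior(cfg)
        post.joint = post.joint * 2.0
        with pytest.raises(ContractViolationError):
            predict_step(post)

    def test_mass_stays_normalized_through_many_steps(self):
        cfg = tiny_config(3)
        post = init_posterior(cfg)
        rng = np.random.default_rng(0)
        for _ in range(30):
            post = predict_step(post)
            assert abs(post.total_mass - 1.0) < 1e-10
            post = update_step(post, float(rng.uniform(0.2, 0.8)))
            assert abs(post.total_mass - 1.0) < 1e-10


class TestUpdateStep:
    def test_point_mass_prior_is_unchanged(self):
        cfg = pinned_config(0.1, 0.1, n_mu=1, mu_range=(0.5, 0.5))
        post = init_posterior(cfg)
        post2 = update_step(post, 0.5)
        assert np.allclose(post2.joint, post.joint)

    def test_two_cell_bayes_rule(self):
        # equi-probable mu in {0.2, 0.8}, SD = 0.1, observe y = 0.8:
        # essentially all mass moves to the 0.8 cell. The exact split follows
        # Bayes' rule with the cell-integrated Gaussian observation model
        # (cell edges at -0.1, 0.5, 1.1), computed here independently.
        from scipy.stats import norm

        cfg = FilterConfig(
            mu=GridDim(points=np.array([0.2, 0.8]), prior=np.array([0.5, 0.5])),
            log_vmu=GridDim.pinned(math.log(0.1)),
            log_sd=GridDim.pinned(math.log(0.1)),
            kmu=GridDim.pinned(0.01),
            vsd=GridDim.pinned(0.01),
        )
        post = update_step(init_posterior(cfg), 0.8)
        l_far = norm.cdf((0.5 - 0.8) / 0.1) - norm.cdf((-0.1 - 0.8) / 0.1)
        l_near = norm.cdf((1.1 - 0.8) / 0.1) - norm.cdf((0.5 - 0.8) / 0.1)
        expected = l_near / (l_near + l_far)
        assert post.marginal("mu")[1] == pytest.approx(expected, abs=1e-12)
        assert post.marginal("mu")[1] > 0.99

    def test_repeated_updates_concentrate_mu(self):
        cfg = pinned_config(1e-12, 0.1, n_mu=25, mu_range=(0.0, 1.0))
        post = init_posterior(cfg)
        last_sd = np.inf
        for _ in range(6):
            post = update_step(post, 0.5)
            marg = post.marginal("mu")
            mean = marg @ cfg.mu.points
            sd = math.sqrt(marg @ (cfg.mu.points - mean) ** 2)
            assert sd < last_sd
            last_sd = sd

    def test_out_of_grid_rating_warns_and_clamps(self):
        cfg = pinned_config(0.1, 0.1, n_mu=5, mu_range=(0.0, 1.0))
        with pytest.warns(UserWarning, match="clamping"):
            update_step(init_posterior(cfg), 4.2)

    def test_underflowed_likelihood_raises(self):
        # belief frozen on mu = 0 with near-zero noise, then a rating of 1
        # arrives: every cell's posterior mass underflows to exact zero
        cfg = FilterConfig(
            mu=GridDim(points=np.array([0.0, 1.0]), prior=np.array([1.0, 0.0])),
            log_vmu=GridDim.pinned(math.log(1e-6)),
            log_sd=GridDim.pinned(math.log(1e-6)),
            kmu=GridDim.pinned(1e-9),
            vsd=GridDim.pinned(1e-9),
        )
        with pytest.raises(DegenerateLikelihoodError):
            update_step(init_posterior(cfg), 1.0)


class TestRunFilter:
    def test_constant_series_settles_on_the_constant(self, default_config):
        series = make_series(np.full(50, 0.5))
        traj = run_filter(series, default_config)
        assert traj.posterior_mean[-1] == pytest.approx(0.5, abs=0.02)
        # no variability to attribute: both scales end below their prior means
        prior_vol = np.mean(np.exp(default_config.log_vmu.points))
        prior_noise = np.mean(np.exp(default_config.log_sd.points))
        assert traj.volatility[-1] < prior_vol
        assert traj.noise[-1] < prior_noise

    def test_missing_block_is_prediction_only(self, default_config):
        vals = np.concatenate([np.full(20, 0.5), np.full(10, np.nan), np.full(10, 0.5)])
        traj = run_filter(make_series(vals), default_config)
        block = slice(20, 30)
        assert np.allclose(np.diff(traj.predicted_mean[block]), 0.0, atol=1e-6)
        assert not traj.observed[block].any()
        # beliefs broaden (noise and volatility drift up toward the prior)
        assert traj.volatility[29] >= traj.volatility[19] - 1e-9

    def test_too_short_series_rejected(self, default_config):
        with pytest.raises(InsufficientDataError):
            run_filter(make_series([0.5]), default_config)

    def test_deterministic(self, short_series, default_config):
        t1 = run_filter(short_series, default_config)
        t2 = run_filter(short_series, default_config)
        assert np.array_equal(t1.volatility, t2.volatility)
        assert np.array_equal(t1.posterior_mean, t2.posterior_mean)

    def test_batch_equals_individual_runs(self, default_config):
        rng = np.random.default_rng(7)
        series = [
            make_series(np.clip(rng.normal(0.5, 0.1, size=n), 0, 1))
            for n in (12, 20, 9)
        ]
        batch = run_filter_batch(series, default_config, chunk_size=3)
        for s, b in zip(series, batch):
            solo = run_filter(s, default_config)
            assert np.allclose(solo.volatility, b.volatility, atol=1e-12)
            assert np.allclose(solo.noise, b.noise, atol=1e-12)

    def test_results_object_surface(self, short_series):
        res = AffectFilter(short_series).fit()
        end = res.endpoint()
        assert end["volatility"] > 0 and end["noise"] > 0
        assert "volatility" in res.summary()
        frame = res.to_frame()
        assert list(frame["day"]) == list(range(1, 21))


def flat_forward_oracle(config, observations):
    """Exhaustive-path oracle: forward recursion on the flattened joint.

    Builds the full joint transition matrix by explicit loops over every
    pair of states (summing over all paths via dynamic programming) and
    applies pointwise Gaussian-mass likelihoods — sharing no code with the
    filter's factorized engine.
    """
    from scipy.stats import norm

    mu = config.mu.points
    lv = config.log_vmu.points
    ls = config.log_sd.points
    km = config.kmu.points
    vs = config.vsd.points
    states = [
        (i, v, s, k, w)
        for i in range(len(mu))
        for v in range(len(lv))
        for s in range(len(ls))
        for k in range(len(km))
        for w in range(len(vs))
    ]
    index = {st: n for n, st in enumerate(states)}

    def kern(points, sd):
        g = np.array([[math.exp(-((b - a) ** 2) / (2 * max(sd, 1e-300) ** 2)) for b in points] for a in points])
        return g / g.sum(axis=1, keepdims=True)

    k_mu = {v: kern(mu, math.exp(lv[v])) for v in range(len(lv))}
    k_lv = {k: kern(lv, km[k]) for k in range(len(km))}
    k_ls = {w: kern(ls, vs[w]) for w in range(len(vs))}

    t_full = np.zeros((len(states), len(states)))
    for (i, v, s, k, w) in states:
        for (i2, v2, s2, k2, w2) in states:
            if k2 != k or w2 != w:
                continue
            # mu moves under the pre-step volatility v
            t_full[index[(i, v, s, k, w)], index[(i2, v2, s2, k2, w2)]] = (
                k_mu[v][i][i2] * k_lv[k][v][v2] * k_ls[w][s][s2]
            )

    # cell-integrated Gaussian likelihood, matching the observation model
    edges = np.concatenate([
        [mu[0] - (mu[1] - mu[0]) / 2], (mu[:-1] + mu[1:]) / 2, [mu[-1] + (mu[-1] - mu[-2]) / 2]
    ])
    p = np.array(
        [
            config.mu.prior[i] * config.log_vmu.prior[v] * config.log_sd.prior[s]
            * config.kmu.prior[k] * config.vsd.prior[w]
            for (i, v, s, k, w) in states
        ]
    )
    history = []
    for y in observations:
        p = t_full.T @ p
        like = np.array(
            [
                norm.cdf((edges[i + 1] - y) / math.exp(ls[s])) - norm.cdf((edges[i] - y) / math.exp(ls[s]))
                for (i, v, s, k, w) in states
            ]
        )
        p = p * like
        p = p / p.sum()
        history.append(p.copy())
    return states, history


class TestOracleEquivalence:
    def test_filter_matches_flat_enumeration(self):
        cfg = tiny_config(3)
        rng = np.random.default_rng(11)
        ys = rng.uniform(0.2, 0.8, size=5)
        states, history = flat_forward_oracle(cfg, ys)

        post = init_posterior(cfg)
        for t, y in enumerate(ys):
            post = update_step(predict_step(post), float(y))
            flat = np.array([post.joint[st] for st in states])
            assert np.max(np.abs(flat - history[t])) < 1e-8

    def test_run_filter_matches_oracle_expectations(self):
        cfg = tiny_config(3)
        rng = np.random.default_rng(12)
        ys = rng.uniform(0.2, 0.8, size=5)
        states, history = flat_forward_oracle(cfg, ys)
        traj = run_filter(make_series(ys), cfg)
        vmu_vals = np.exp(cfg.log_vmu.points)
        for t in range(5):
            e_vmu = sum(p * vmu_vals[st[1]] for p, st in zip(history[t], states))
            assert traj.volatility[t] == pytest.approx(e_vmu, abs=1e-8)


class TestKalmanLimit:
    def test_first_observation_diffuse_prior(self):
        series = make_series([0.7, 0.6, 0.5])
        means = kalman_reference(series, 0.05, 0.1)
        assert means[0] == pytest.approx(0.7, abs=1e-6)

    def test_infinite_signal_to_noise_tracks_data(self):
        series = make_series([0.2, 0.9, 0.4, 0.6])
        means = kalman_reference(series, 50.0, 1e-4)
        assert np.allclose(means, series.values, atol=1e-4)

    def test_grid_filter_agrees_with_closed_form(self):
        vmu, sd = 0.05, 0.10
        cfg = pinned_config(vmu, sd)
        rng = np.random.default_rng(21)
        for _ in range(3):
            params = GenerativeParams(mu0=0.5, vmu0=vmu, sd0=sd, n_steps=50)
            _, series = simulate_subject(params, int(rng.integers(2**31)))
            traj = run_filter(series, cfg)
            ref = kalman_reference(series, vmu, sd)
            rmse = np.sqrt(np.mean((traj.posterior_mean - ref) ** 2))
            assert rmse <= 0.01

    def test_missing_data_rejected(self):
        series = make_series([0.5, np.nan, 0.5])
        with pytest.raises(ContractViolationError):
            kalman_reference(series, 0.1, 0.1)


class TestIdentifiability:
    def test_volatile_and_noisy_series_separated(self, default_config):
        """Series with matched marginal SD but opposite cause are told apart.

        High-volatility/low-noise vs low-volatility/high-noise regimes are
        calibrated to produce similar overall rating SD; the filter should
        assign them opposite signs of E[vmu_50] - E[SD_50] ordering.
        """
        hi_v = GenerativeParams(mu0=0.5, vmu0=0.03, sd0=0.02, n_steps=50)
        hi_n = GenerativeParams(mu0=0.5, vmu0=0.005, sd0=0.15, n_steps=50)
        series, pairs = [], 50
        for seed in range(pairs):
            series.append(simulate_subject(hi_v, 1000 + seed)[1])
            series.append(simulate_subject(hi_n, 2000 + seed)[1])
        trajs = run_filter_batch(series, default_config)
        wins = 0
        for j in range(pairs):
            a, b = trajs[2 * j], trajs[2 * j + 1]
            gap_a = a.volatility[-1] - a.noise[-1]
            gap_b = b.volatility[-1] - b.noise[-1]
            wins += gap_a > gap_b
        assert wins >= 0.8 * pairs
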