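"""Sampler correctness, mode/HPDI estimators, and method dispatch."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from xciskew import (
    PriorSpec,
    SamplerConfig,
    SimulationConfig,
    estimate_gamma,
    hpdi,
    posterior_mode,
    sample_posterior,
    simulate_mixed_dataset,
)
from xciskew.model import build_posterior, encode_genotypes


class _GaussianMeanToy:
    """Conjugate toy: y_i ~ N(mu, sigma^2) known sigma, mu ~ N(0, tau^2)."""

    param_names = ["mu"]

    def __init__(self, y, sigma=1.0, tau=10.0):
        self.y = np.asarray(y, float)
        self.sigma2 = sigma ** 2
        self.tau2 = tau ** 2

    def initial_position(self, rng):
        return rng.normal(size=1)

    def unpack(self, x):
        return {"mu": x[0]}

    def logp_and_grad(self, x):
        mu = x[0]
        r = self.y - mu
        logp = -0.5 * float(r @ r) / self.sigma2 - 0.5 * mu ** 2 / self.tau2
        grad = np.array([float(r.sum()) / self.sigma2 - mu / self.tau2])
        return logp, grad

    def posterior_moments(self):
        n = len(self.y)
        var = 1.0 / (n / self.sigma2 + 1.0 / self.tau2)
        return var * self.y.sum() / self.sigma2, var


class TestSampler:
    def test_conjugate_toy_recovers_closed_form(self, rng):
        toy = _GaussianMeanToy(rng.normal(1.3, 1.0, size=40))
        draws = sample_posterior(
            toy, SamplerConfig(n_chains=2, n_iterations=1500, n_warmup=500, seed=4)
        )
        mu = draws.stacked("mu")
        true_mean, true_var = toy.posterior_moments()
        # 2000 correlated draws; allow a conservative effective sample size
        mcse = np.sqrt(true_var / (len(mu) / 10))
        assert mu.mean() == pytest.approx(true_mean, abs=3 * mcse)
        assert mu.var() == pytest.approx(true_var, rel=0.3)
        assert draws.max_rhat < 1.05

    def test_retained_draw_count(self, rng):
        toy = _GaussianMeanToy(rng.normal(size=10))
        cfg = SamplerConfig(n_chains=3, n_iterations=400, n_warmup=150, seed=1)
        draws = sample_posterior(toy, cfg)
        assert draws.n_retained == cfg.n_retained == 750

    def test_reproducible_given_seed(self, rng):
        toy = _GaussianMeanToy(rng.normal(size=15))
        cfg = SamplerConfig(n_chains=2, n_iterations=300, n_warmup=100, seed=7)
        d1 = sample_posterior(toy, cfg)
        d2 = sample_posterior(toy, cfg)
        assert np.array_equal(d1.params["mu"], d2.params["mu"])

    def test_warmup_must_be_shorter(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, n_warmup=100)


class TestPosteriorMode:
    def test_degenerate_draws(self):
        assert posterior_mode(np.full(200, 0.73)) == pytest.approx(0.73)

    def test_truncated_normal_oracle(self, rng):
        a, b = (0 - 0.8) / 0.05, (2 - 0.8) / 0.05
        draws = truncnorm.rvs(a, b, loc=0.8, scale=0.05, size=100_000,
                              random_state=rng)
        assert posterior_mode(draws) == pytest.approx(0.80, abs=0.01)

    def test_boundary_mass_stays_in_support(self, rng):
        a, b = (0 - 0.02) / 0.05, (2 - 0.02) / 0.05
        draws = truncnorm.rvs(a, b, loc=0.02, scale=0.05, size=50_000,
                              random_state=rng)
        mode = posterior_mode(draws)
        assert 0.0 <= mode <= 0.1

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            posterior_mode(np.linspace(0, 2, 50))


class TestHPDI:
    def test_uniform_width(self, rng):
        draws = rng.uniform(0, 2, size=100_000)
        lo, hi = hpdi(draws, 0.95)
        assert hi - lo == pytest.approx(1.9, abs=0.02)

    def test_normal_quantile_oracle(self, rng):
        draws = rng.normal(size=100_000)
        lo, hi = hpdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_all_equal_zero_width(self):
        lo, hi = hpdi(np.full(500, 1.2))
        assert lo == hi == 1.2

    def test_contains_requested_mass(self, rng):
        draws = rng.normal(size=5000)
        lo, hi = hpdi(draws, 0.9)
        inside = np.mean((draws >= lo) & (draws <= hi))
        assert inside >= 0.9

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpdi(np.linspace(0, 2, 50))


@pytest.fixture(scope="module")
def mixed_data():
    return simulate_mixed_dataset(
        SimulationConfig(n_pedigrees_per_structure=4, n_unrelated_females=40,
                         gamma=1.0, seed=99)
    )


FAST = SamplerConfig(n_chains=2, n_iterations=600, n_warmup=250, seed=5)


class TestDispatch:
    def test_bnp_rejects_unrelated(self, mixed_data):
        with pytest.raises(ValueError, match="pedigree females only"):
            estimate_gamma(mixed_data, "BNP", FAST)

    def test_bn_rejects_pedigree(self, mixed_data):
        with pytest.raises(ValueError, match="unrelated females only"):
            estimate_gamma(mixed_data, "BN", FAST)

    def test_unknown_method(self, mixed_data):
        with pytest.raises(ValueError, match="unknown method"):
            estimate_gamma(mixed_data, "XYZ", FAST)

    def test_bn_has_no_random_effect(self, mixed_data):
        res = estimate_gamma(mixed_data.unrelated_only(), "BN", FAST)
        assert "sigma_g" not in res.draws.params
        assert "sigma_e" in res.draws.params
        assert 0.0 <= res.gamma_hat <= 2.0

    def test_bnm_vs_bum_differ_only_in_prior(self, mixed_data):
        rn = estimate_gamma(mixed_data, "BNM", FAST)
        ru = estimate_gamma(mixed_data, "BUM", FAST)
        assert rn.method == "BNM" and ru.method == "BUM"
        # same machinery, different prior: estimates close relative to width
        assert abs(rn.gamma_hat - ru.gamma_hat) < max(rn.width, ru.width)

    def test_result_fields(self, mixed_data):
        res = estimate_gamma(mixed_data, "BNM", FAST)
        lo, hi = res.hpdi
        assert 0.0 <= lo <= hi <= 2.0
        assert res.width == pytest.approx(hi - lo)
        assert 0.0 <= res.gamma_hat <= 2.0
        assert isinstance(res.converged, bool)


class _DenseQuantitative:
    """Direct multivariate-normal log-posterior (no eigen rotation).

    Independent sampling path used to check that the EVD reparameterization
    leaves the posterior unchanged.
    """

    def __init__(self, data, prior):
        design = encode_genotypes(data.genotypes)
        self.x1, self.x2 = design.x1, design.x2
        self.y = data.traits
        self.z = data.covariates
        self.phi = data.relatedness.values
        self.m = self.z.shape[1]
        self.prior = prior
        self.param_names = ["gamma", "beta"] + [
            f"a{j + 1}" for j in range(self.m)
        ] + ["sigma_g", "sigma_e"]

    def initial_position(self, rng):
        gamma = rng.uniform(0.2, 1.8)
        return np.concatenate([
            [np.log(gamma / (2 - gamma)), rng.normal()],
            rng.normal(size=self.m),
            np.log(rng.exponential(1.0, size=2) + 0.1),
        ])

    def unpack(self, x):
        from scipy.special import expit

        out = {"gamma": 2 * expit(x[0]), "beta": x[1]}
        for j in range(self.m):
            out[f"a{j + 1}"] = x[2 + j]
        out["sigma_g"] = np.exp(x[2 + self.m])
        out["sigma_e"] = np.exp(x[3 + self.m])
        return out

    def logp_and_grad(self, x):
        from scipy.special import expit

        m = self.m
        s = expit(x[0])
        gamma, beta, a = 2 * s, x[1], x[2:2 + m]
        sg, se = np.exp(min(x[2 + m], 40)), np.exp(min(x[3 + m], 40))
        n = len(self.y)
        cov = sg ** 2 * self.phi + se ** 2 * np.eye(n)
        mu = beta * gamma * self.x1 + beta * (2 - gamma) * self.x2 + self.z @ a
        r = self.y - mu
        cinv_r = np.linalg.solve(cov, r)
        sign, logdet = np.linalg.slogdet(cov)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ cinv_r))
        # priors (same as the package's) + transforms
        lp = ll - 0.5 * (gamma - 1) ** 2 - 0.5 * beta ** 2 / 100 \
            - 0.5 * float(a @ a) / 100 - sg - se \
            + x[2 + m] + x[3 + m] + np.log(2) + np.log(s) + np.log1p(-s)
        grad = np.empty_like(x)
        dmu_gamma = beta * (self.x1 - self.x2)
        grad[0] = (float(cinv_r @ dmu_gamma) - (gamma - 1)) * 2 * s * (1 - s) \
            + 1 - 2 * s
        grad[1] = float(cinv_r @ (gamma * self.x1 + (2 - gamma) * self.x2)) \
            - beta / 100
        grad[2:2 + m] = self.z.T @ cinv_r - a / 100
        cinv = np.linalg.inv(cov)
        for slot, dcov, uterm in (
            (2 + m, 2 * sg ** 2 * self.phi, 1 - sg),
            (3 + m, 2 * se ** 2 * np.eye(n), 1 - se),
        ):
            grad[slot] = 0.5 * (
                float(cinv_r @ dcov @ cinv_r) - float(np.trace(cinv @ dcov))
            ) + uterm
        return lp, grad


def test_evd_and_dense_posteriors_agree(rng):
    """Sampling the rotated model equals sampling the direct MVN model."""
    data = simulate_mixed_dataset(
        SimulationConfig(n_pedigrees_per_structure=1, n_unrelated_females=8,
                         gamma=1.0, seed=77)
    )
    assert data.nf <= 20
    prior = PriorSpec()
    cfg = SamplerConfig(n_chains=2, n_iterations=2000, n_warmup=700, seed=13)
    fast = sample_posterior(build_posterior(data, prior), cfg)
    dense = sample_posterior(_DenseQuantitative(data, prior), cfg)
    for name in ("gamma", "beta", "sigma_g", "sigma_e"):
        a = fast.stacked(name)
        b = dense.stacked(name)
        # conservative MCSE: effective sample size of n/10 per path
        se = np.sqrt(a.var() / (len(a) / 10) + b.var() / (len(b) / 10))
        assert abs(a.mean() - b.mean()) < 3 * se, name
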