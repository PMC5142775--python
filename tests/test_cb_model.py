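import numpy as np
import pytest
from scipy.special import expit

from nmaloo import (
    ArmRecord,
    CBPriors,
    CBTruth,
    DesignSpec,
    MCMCConfig,
    NMANetwork,
    fit_cb,
    or_from_d,
    sample_design,
    simulate_cb,
)


def _binom_ll(y, n, p):
    p = np.clip(p, 1e-300, 1 - 1e-15)
    return y * np.log(p) + (n - y) * np.log1p(-p)


def pairwise_grid_posterior(arms, mu_sd=10.0):
    """Independent oracle for the two-treatment degenerate NMA: the joint
    posterior of (d, sigma) for a Bayesian random-effects pairwise
    meta-analysis, computed by grid integration.

    Trial baselines and contrasts are integrated out numerically; the
    sigma-dependent convolution uses Gauss-Hermite nodes so the sigma -> 0
    limit is exact.  Priors match the sampler's defaults.
    """
    mu_g = np.linspace(-8, 8, 401)
    de_g = np.linspace(-5, 5, 801)
    dmu = mu_g[1] - mu_g[0]
    hs = []
    for (y1, n1, y2, n2) in arms:
        A = _binom_ll(y1, n1, expit(mu_g)) - 0.5 * (mu_g / mu_sd) ** 2
        B = _binom_ll(y2, n2, expit(mu_g[:, None] + de_g[None, :]))
        F = np.exp(A[:, None] + B - (A.max() + B.max()))
        hs.append(F.sum(0) * dmu)
    z, w = np.polynomial.hermite_e.hermegauss(61)
    w = w / np.sqrt(2 * np.pi)
    d_g = np.linspace(-2.5, 2.5, 201)
    s_g = np.linspace(1e-4, 2.0, 201)
    logpost = np.zeros((len(d_g), len(s_g)))
    for h in hs:
        pts = d_g[:, None, None] + s_g[None, :, None] * z[None, None, :]
        L = (np.interp(pts, de_g, h) * w).sum(-1)
        logpost += np.log(np.clip(L, 1e-300, None))
    logpost += -0.5 * (d_g[:, None] / mu_sd) ** 2  # N(0, mu_sd^2) prior on d
    wgt = np.exp(logpost - logpost.max())
    wgt /= wgt.sum()
    d_mean = float((wgt.sum(1) * d_g).sum())
    s_mean = float((wgt.sum(0) * s_g).sum())
    return d_mean, s_mean


@pytest.fixture(scope="module")
def post():
    truth = CBTruth(baseline_mean=-0.3, baseline_sd=0.4, d=(0.4, -0.2, 0.1), sigma=0.2)
    design = sample_design(DesignSpec(4, 14, seed=8))
    net = simulate_cb(design, truth, per_arm_n=300, seed=8)
    return fit_cb(net, MCMCConfig.test_profile(seed=81))


class TestORFromD:
    def test_versus_reference_is_exp_d(self, post):
        ors = or_from_d(post, "T2", post.reference)
        assert np.allclose(ors, np.exp(post.d_samples[:, 1]))

    def test_reciprocal_identity_per_draw(self, post):
        assert np.allclose(or_from_d(post, "T2", "T3") * or_from_d(post, "T3", "T2"), 1.0)

    def test_consistency_identity_exact_per_draw(self, post):
        lhs = or_from_d(post, "T2", "T3")
        rhs = or_from_d(post, "T2", "T4") * or_from_d(post, "T4", "T3")
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=0)

    def test_unknown_treatment_rejected(self, post):
        with pytest.raises(KeyError):
            or_from_d(post, "T2", "TX")

    def test_same_treatment_rejected(self, post):
        with pytest.raises(ValueError):
            or_from_d(post, "T2", "T2")


class TestFitCB:
    def test_two_treatment_network_matches_pairwise_grid_oracle(self):
        """The degenerate two-treatment NMA equals a Bayesian random-effects
        pairwise meta-analysis; the sampler must agree with an independent
        grid-integration posterior."""
        rng = np.random.default_rng(5)
        arm_data, recs = [], []
        for i in range(6):
            mu = rng.normal(-0.3, 0.5)
            delta = rng.normal(0.6, 0.25)
            n1, n2 = 80, 90
            y1 = int(rng.binomial(n1, expit(mu)))
            y2 = int(rng.binomial(n2, expit(mu + delta)))
            arm_data.append((y1, n1, y2, n2))
            recs += [ArmRecord(f"S{i+1}", "T1", y1, n1),
                     ArmRecord(f"S{i+1}", "T2", y2, n2)]
        d_oracle, s_oracle = pairwise_grid_posterior(arm_data)
        net = NMANetwork(("T1", "T2"), tuple(recs), "beneficial", "pairwise")
        cfg = MCMCConfig.test_profile(seed=3, n_adapt=1500, n_burnin=1500, n_iter=8000)
        post = fit_cb(net, cfg)
        assert post.d_samples[:, 1].mean() == pytest.approx(d_oracle, abs=0.03)
        assert post.sigma_samples.mean() == pytest.approx(s_oracle, abs=0.06)

    def test_no_signal_data_keeps_d_near_zero(self):
        arms = tuple(
            ArmRecord(f"S{i}", t, 30, 100)
            for i in range(5) for t in ("T1", "T2", "T3")
        )
        net = NMANetwork(("T1", "T2", "T3"), arms)
        cfg = MCMCConfig(n_chains=2, n_adapt=400, n_burnin=300, n_iter=1200, thin=1, seed=4)
        post = fit_cb(net, cfg, CBPriors(sigma_max=0.01))
        assert np.all(np.abs(post.d_samples.mean(axis=0)) < 0.05)

    def test_reference_invariance_of_or(self):
        truth = CBTruth(baseline_mean=0.0, baseline_sd=0.4, d=(0.5, -0.3), sigma=0.15)
        design = sample_design(DesignSpec(3, 12, seed=12))
        net = simulate_cb(design, truth, per_arm_n=400, seed=12)
        cfg = MCMCConfig.test_profile(seed=31)
        p1 = fit_cb(net, cfg, reference="T1")
        p3 = fit_cb(net, cfg, reference="T3")
        or_a = float(np.median(or_from_d(p1, "T2", "T3")))
        or_b = float(np.median(or_from_d(p3, "T2", "T3")))
        assert or_a == pytest.approx(or_b, rel=0.08)

    def test_baseline_map_uses_lowest_indexed_treatment(self):
        arms = (
            ArmRecord("S1", "T2", 5, 20), ArmRecord("S1", "T3", 5, 20),
            ArmRecord("S2", "T1", 5, 20), ArmRecord("S2", "T3", 5, 20),
            ArmRecord("S3", "T1", 5, 20), ArmRecord("S3", "T2", 5, 20),
            ArmRecord("S4", "T2", 5, 20), ArmRecord("S4", "T3", 5, 20),
            ArmRecord("S5", "T1", 5, 20), ArmRecord("S5", "T3", 5, 20),
            ArmRecord("S6", "T1", 5, 20), ArmRecord("S6", "T2", 5, 20),
        )
        net = NMANetwork(("T1", "T2", "T3"), arms)
        post = fit_cb(net, MCMCConfig(n_chains=2, n_adapt=100, n_burnin=50,
                                      n_iter=100, thin=1, seed=2))
        assert post.baseline_map == {
            "S1": "T2", "S2": "T1", "S3": "T1", "S4": "T2", "S5": "T1", "S6": "T1",
        }
        assert np.all(post.d_samples[:, 0] == 0.0)  # reference column pinned

    def test_unknown_reference_rejected(self, toy_network, tiny_mcmc):
        with pytest.raises(KeyError):
            fit_cb(toy_network, tiny_mcmc, reference="TX")

    def test_disconnected_network_rejected(self, tiny_mcmc):
        arms = (
            ArmRecord("S1", "T1", 1, 10), ArmRecord("S1", "T2", 2, 10),
            ArmRecord("S2", "T3", 3, 10), ArmRecord("S2", "T4", 4, 10),
        )
        net = NMANetwork(("T1", "T2", "T3", "T4"), arms)
        with pytest.raises(ValueError, match="disconnected"):
            fit_cb(net, tiny_mcmc)
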