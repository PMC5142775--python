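"""Arm-based (AB) Bayesian hierarchical NMA model.

The model places a probit-linked hierarchical structure directly on arm-level
event probabilities::

    y_ik ~ Binomial(n_ik, p_ik),   Phi^{-1}(p_ik) = mu_k + sigma * v_ik,
    (v_i1, ..., v_iK)^T ~ MVN(0, R_K),  R_K exchangeable with correlation rho.

Because R_K is exchangeable, the random-effect vector restricted to a trial's
treatment set S_i is itself MVN with the same structure, so each trial only
carries |S_i| latent effects.  The population-averaged event rate has the
closed form pi_k = Phi(mu_k / sqrt(1 + sigma^2)); marginal odds ratios and
ranking probabilities (Pbest) are derived from the pi_k draws.

Sampling uses adaptive Metropolis-within-Gibbs with a non-centered latent
parameterization (standardized v, scaled by sigma) for stability near
sigma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import ndtr, ndtri

from .mcmc import (
    MCMCConfig,
    ScaleAdapter,
    binom_loglik,
    chain_rng,
    compute_rhat,
    convergence_warnings,
    exch_corr_logpdf,
)
from .network_data import NMANetwork, comparison_graph
import networkx as nx

Direction = Literal["beneficial", "harmful"]


@dataclass(frozen=True)
class ABPriors:
    """Vague default priors: mu_k ~ N(0, mu_sd^2), sigma ~ U(0, sigma_max),
    rho ~ U(-1/(K-1), 1)."""

    mu_sd: float = 10.0
    sigma_max: float = 5.0


# -- closed-form derived quantities ----------------------------------------

def pop_avg_risk(mu, sigma):
    """Population-averaged event rate Phi(mu / sqrt(1 + sigma^2)).

    This is the marginal mean of p = Phi(mu + sigma Z), Z ~ N(0,1); it
    shrinks toward 1/2 as heterogeneity grows.  Vectorized over both
    arguments.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return ndtr(mu / np.sqrt(1.0 + sigma * sigma))


def marginal_or(pi_k, pi_l):
    """Marginal odds ratio [pi_k/(1-pi_k)] / [pi_l/(1-pi_l)]."""
    pi_k = np.asarray(pi_k, dtype=float)
    pi_l = np.asarray(pi_l, dtype=float)
    if np.any((pi_k <= 0) | (pi_k >= 1) | (pi_l <= 0) | (pi_l >= 1)):
        raise ValueError("risks must lie strictly inside (0, 1)")
    return (pi_k / (1.0 - pi_k)) / (pi_l / (1.0 - pi_l))


def pbest(pi_samples: np.ndarray, direction: Direction) -> np.ndarray:
    """Probability of being the best treatment, per treatment.

    For a beneficial outcome the best treatment has the highest event rate;
    for a harmful outcome the lowest.  Ties within a draw split the draw's
    mass equally among the tied treatments, so the vector sums to one.
    """
    pi = np.asarray(pi_samples, dtype=float)
    if pi.ndim != 2 or pi.shape[0] == 0:
        raise ValueError("pi_samples must be a non-empty (draws, K) array")
    if direction not in ("beneficial", "harmful"):
        raise ValueError(f"unknown direction {direction!r}")
    extreme = pi.max(axis=1) if direction == "beneficial" else pi.min(axis=1)
    ties = pi == extreme[:, None]
    weights = ties / ties.sum(axis=1, keepdims=True)
    return weights.mean(axis=0)


def or_matrix_from_risks(pi: np.ndarray) -> np.ndarray:
    """K x K marginal odds-ratio matrix from a vector of risks (OR_kk = 1)."""
    odds = np.asarray(pi) / (1.0 - np.asarray(pi))
    return odds[:, None] / odds[None, :]


# -- posterior containers ---------------------------------------------------

@dataclass(frozen=True)
class ABPosterior:
    """Posterior draws of the AB model (chains pooled after warm-up)."""

    treatments: tuple[str, ...]
    mu_samples: np.ndarray        # (draws, K)
    sigma_samples: np.ndarray     # (draws,)
    rho_samples: np.ndarray       # (draws,)
    rhat: dict[str, float]
    warnings: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.mu_samples.shape[0]

    def pi_samples(self) -> np.ndarray:
        return pop_avg_risk(self.mu_samples, self.sigma_samples[:, None])


@dataclass(frozen=True)
class ABDerived:
    """Derived summaries: risk draws, point risks, OR draws and Pbest."""

    treatments: tuple[str, ...]
    pi_samples: np.ndarray        # (draws, K)
    pi_point: np.ndarray          # (K,) posterior mean (or median) risks
    or_samples: np.ndarray        # (draws, K, K)
    or_point: np.ndarray          # (K, K) plug-in OR from pi_point
    pbest: np.ndarray             # (K,)
    direction: str

    def best_treatment(self) -> tuple[str, float]:
        """Best treatment by Pbest; ties resolved to the lowest index."""
        idx = int(np.argmax(self.pbest))
        return self.treatments[idx], float(self.pbest[idx])

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1.0 - level) / 2.0
        return np.quantile(self.pi_samples, [lo, 1.0 - lo], axis=0).T


def derive_ab(
    post: ABPosterior,
    direction: Direction,
    point_estimate: Literal["mean", "median"] = "mean",
) -> ABDerived:
    """Population-averaged risks, marginal ORs and Pbest from an AB fit."""
    pi = post.pi_samples()
    pi_point = np.mean(pi, axis=0) if point_estimate == "mean" else np.median(pi, axis=0)
    odds = pi / (1.0 - pi)
    or_samples = odds[:, :, None] / odds[:, None, :]
    return ABDerived(
        treatments=post.treatments,
        pi_samples=pi,
        pi_point=pi_point,
        or_samples=or_samples,
        or_point=or_matrix_from_risks(pi_point),
        pbest=pbest(pi, direction),
        direction=direction,
    )


# -- sampler ----------------------------------------------------------------

class _ABData:
    """Padded and flat views of the arm-level data for vectorized updates."""

    def __init__(self, net: NMANetwork):
        studies = net.study_ids
        self.I = len(studies)
        self.K = net.n_treatments
        arms_per = [net.arms_of(s) for s in studies]
        self.row_count = np.array([len(a) for a in arms_per])
        self.A = int(self.row_count.max())
        trial_idx, arm_idx, y, n, t = [], [], [], [], []
        for i, arms in enumerate(arms_per):
            for j, arm in enumerate(arms):
                trial_idx.append(i)
                arm_idx.append(j)
                y.append(arm.events)
                n.append(arm.sample_size)
                t.append(net.treatment_index(arm.treatment_id))
        self.trial_idx = np.array(trial_idx)
        self.arm_idx = np.array(arm_idx)
        self.y = np.array(y, dtype=float)
        self.n = np.array(n, dtype=float)
        self.t = np.array(t)
        self.n_arms = len(y)

    def init_mu(self) -> np.ndarray:
        """Crude pooled probit rates as a starting point."""
        events = np.bincount(self.t, weights=self.y, minlength=self.K)
        totals = np.bincount(self.t, weights=self.n, minlength=self.K)
        rate = np.clip((events + 0.5) / (totals + 1.0), 1e-4, 1 - 1e-4)
        return ndtri(rate)


def _run_ab_chain(
    data: _ABData,
    priors: ABPriors,
    config: MCMCConfig,
    chain: int,
    rho_lo: float,
):
    rng = chain_rng(config, chain)
    I, K = data.I, data.K
    mu = data.init_mu() + 0.05 * rng.standard_normal(K)
    sigma = 0.3 * (1.0 + 0.1 * rng.standard_normal())
    sigma = float(np.clip(sigma, 0.02 * priors.sigma_max, 0.8 * priors.sigma_max))
    rho = float(np.clip(0.2, rho_lo + 0.05, 0.95))
    u = np.zeros((I, data.A))

    ad_u = ScaleAdapter(I, 0.5)
    ad_mu = ScaleAdapter(K, 0.2)
    ad_sig = ScaleAdapter((), 0.2)
    ad_rho = ScaleAdapter((), 0.2)

    ti, ai, t = data.trial_idx, data.arm_idx, data.t
    y, n = data.y, data.n
    mu_var = priors.mu_sd ** 2

    def arm_loglik(mu_, sigma_, u_):
        eta = mu_[t] + sigma_ * u_[ti, ai]
        return binom_loglik(y, n, ndtr(eta))

    ll = arm_loglik(mu, sigma, u)
    ll_trial = np.bincount(ti, weights=ll, minlength=I)
    pri_u = exch_corr_logpdf(u, data.row_count, rho)

    n_warm = config.n_adapt + config.n_burnin
    total = n_warm + config.n_iter
    kept = config.n_iter // config.thin
    mu_out = np.empty((kept, K))
    sig_out = np.empty(kept)
    rho_out = np.empty(kept)
    kidx = 0

    for it in range(total):
        adapting = it < config.n_adapt

        # latent effects, one vector proposal per trial
        prop_u = u.copy()
        prop_u[ti, ai] += ad_u.scale[ti] * rng.standard_normal(data.n_arms)
        ll_new = arm_loglik(mu, sigma, prop_u)
        ll_trial_new = np.bincount(ti, weights=ll_new, minlength=I)
        pri_new = exch_corr_logpdf(prop_u, data.row_count, rho)
        dlp = (pri_new - pri_u) + (ll_trial_new - ll_trial)
        acc = np.log(rng.random(I)) < dlp
        if np.any(acc):
            u[acc] = prop_u[acc]
            pri_u = np.where(acc, pri_new, pri_u)
            ll_trial = np.where(acc, ll_trial_new, ll_trial)
            arm_acc = acc[ti]
            ll = np.where(arm_acc, ll_new, ll)
        if adapting:
            ad_u.update(acc.astype(float))

        # treatment effects: likelihood factorizes over arms, so
        # coordinate-wise accept/reject is valid in parallel
        prop_mu = mu + ad_mu.scale * rng.standard_normal(K)
        ll_new = arm_loglik(prop_mu, sigma, u)
        dll_k = np.bincount(t, weights=ll_new - ll, minlength=K)
        dpri_k = -0.5 * (prop_mu**2 - mu**2) / mu_var
        acc_k = np.log(rng.random(K)) < dll_k + dpri_k
        if np.any(acc_k):
            mu = np.where(acc_k, prop_mu, mu)
            ll = arm_loglik(mu, sigma, u)
            ll_trial = np.bincount(ti, weights=ll, minlength=I)
        if adapting:
            ad_mu.update(acc_k.astype(float))

        # heterogeneity SD
        prop_s = sigma + ad_sig.scale * rng.standard_normal()
        if 0.0 < prop_s < priors.sigma_max:
            ll_new = arm_loglik(mu, prop_s, u)
            if np.log(rng.random()) < ll_new.sum() - ll.sum():
                sigma = float(prop_s)
                ll = ll_new
                ll_trial = np.bincount(ti, weights=ll, minlength=I)
                acc_s = 1.0
            else:
                acc_s = 0.0
        else:
            acc_s = 0.0
        if adapting:
            ad_sig.update(acc_s)

        # exchangeable correlation (prior of u only)
        prop_r = rho + ad_rho.scale * rng.standard_normal()
        if rho_lo + 1e-6 < prop_r < 1.0 - 1e-6:
            pri_new = exch_corr_logpdf(u, data.row_count, prop_r)
            if np.log(rng.random()) < pri_new.sum() - pri_u.sum():
                rho = float(prop_r)
                pri_u = pri_new
                acc_r = 1.0
            else:
                acc_r = 0.0
        else:
            acc_r = 0.0
        if adapting:
            ad_rho.update(acc_r)

        if it >= n_warm and (it - n_warm) % config.thin == 0 and kidx < kept:
            mu_out[kidx] = mu
            sig_out[kidx] = sigma
            rho_out[kidx] = rho
            kidx += 1

    return mu_out[:kidx], sig_out[:kidx], rho_out[:kidx]


def fit_ab(
    net: NMANetwork,
    config: MCMCConfig,
    priors: ABPriors | None = None,
    check_connected: bool = True,
) -> ABPosterior:
    """Fit the AB model by MCMC and return pooled posterior draws.

    Raises on a disconnected network (indirect comparisons across components
    are undefined; ``check_connected=False`` skips this, used by the
    group-split inconsistency model where arm-level fixed effects remain
    identifiable without a connected comparison graph).  A convergence
    warning is attached when any split-R̂ exceeds ``config.rhat_threshold``.
    """
    priors = priors or ABPriors()
    if check_connected and not nx.is_connected(comparison_graph(net)):
        raise ValueError(f"network {net.name!r} is disconnected; cannot fit NMA")
    data = _ABData(net)
    rho_lo = -1.0 / (data.K - 1) if data.K > 1 else -1.0 + 1e-9

    mu_ch, sig_ch, rho_ch = [], [], []
    for c in range(config.n_chains):
        mu_s, sig_s, rho_s = _run_ab_chain(data, priors, config, c, rho_lo)
        mu_ch.append(mu_s)
        sig_ch.append(sig_s)
        rho_ch.append(rho_s)
    mu_arr = np.stack(mu_ch)      # (chains, draws, K)
    sig_arr = np.stack(sig_ch)
    rho_arr = np.stack(rho_ch)

    rhat = compute_rhat({"mu": mu_arr, "sigma": sig_arr, "rho": rho_arr})
    warns = convergence_warnings(rhat, config.rhat_threshold)
    return ABPosterior(
        treatments=net.treatments,
        mu_samples=mu_arr.reshape(-1, data.K),
        sigma_samples=sig_arr.ravel(),
        rho_samples=rho_arr.ravel(),
        rhat=rhat,
        warnings=warns,
    )


def ab_summary(post: ABPosterior, derived: ABDerived, level: float = 0.95) -> dict:
    """JSON-ready summary: risk means, credible intervals, Pbest, R-hat."""
    ci = derived.credible_interval(level)
    return {
        "treatments": list(post.treatments),
        "pi_mean": [float(x) for x in derived.pi_point],
        "pi_ci": [[float(a), float(b)] for a, b in ci],
        "pbest": [float(x) for x in derived.pbest],
        "sigma_mean": float(post.sigma_samples.mean()),
        "rho_mean": float(post.rho_samples.mean()),
        "rhat": {k: v for k, v in post.rhat.items() if "[" not in k},
        "warnings": list(post.warnings),
    }
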