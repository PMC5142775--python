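"""Contrast-based (CB) Bayesian hierarchical NMA model (Lu & Ades form).

The model works on within-trial contrasts relative to each trial's baseline
treatment b(i) (the lowest-indexed treatment in S_i by convention)::

    y_ik ~ Binomial(n_ik, p_ik),
    logit(p_ik) = mu_i + X_ik * delta_{i,b(i),k},
    (delta_{i,b(i),k}, k in S_i \\ b(i)) ~ MVN(d_{b(i)k}, V),

with V the homogeneous-variance exchangeable covariance with correlation
one half (var sigma^2, cov sigma^2/2).  Consistency is built in through the
basic parameters d_bk relative to the network reference b:
d_kl = d_bk - d_bl, and OR_kl = exp(d_kl) holds exactly per posterior draw.

The sampler is Metropolis-within-Gibbs: trial baselines and contrast vectors
get adaptive random-walk updates (vectorized across trials, which are
conditionally independent), the basic parameters d have a fully conjugate
Gaussian conditional and are drawn by exact Gibbs, and the heterogeneity SD
gets a scalar random walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.special import expit, logit

from .mcmc import (
    MCMCConfig,
    ScaleAdapter,
    binom_loglik,
    chain_rng,
    compute_rhat,
    convergence_warnings,
    half_exch_cov_logpdf,
)
from .network_data import NMANetwork, comparison_graph


@dataclass(frozen=True)
class CBPriors:
    """Vague defaults: mu_i ~ N(0, mu_sd^2) iid, d_bk ~ N(0, d_sd^2),
    sigma ~ U(0, sigma_max)."""

    mu_sd: float = 10.0
    d_sd: float = 10.0
    sigma_max: float = 5.0


@dataclass(frozen=True)
class CBPosterior:
    """Posterior draws of the CB model.

    ``d_samples`` has one column per treatment in network order with the
    reference column identically zero, so contrasts are simple column
    differences.
    """

    treatments: tuple[str, ...]
    reference: str
    d_samples: np.ndarray         # (draws, K), reference column == 0
    sigma_samples: np.ndarray     # (draws,)
    baseline_samples: np.ndarray  # (draws, I)
    baseline_map: dict[str, str]  # study -> baseline treatment b(i)
    rhat: dict[str, float]
    warnings: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.d_samples.shape[0]

    def d_point(self, point_estimate: str = "median") -> np.ndarray:
        if point_estimate == "mean":
            return self.d_samples.mean(axis=0)
        return np.median(self.d_samples, axis=0)


def or_from_d(post: CBPosterior, k: str, l: str) -> np.ndarray:
    """Per-draw OR_kl = exp(d_bk - d_bl); exact consistency by construction."""
    if k == l:
        raise ValueError("treatments must differ")
    ik = post.treatments.index(k) if k in post.treatments else None
    il = post.treatments.index(l) if l in post.treatments else None
    if ik is None or il is None:
        raise KeyError(f"unknown treatment {(k if ik is None else l)!r}")
    return np.exp(post.d_samples[:, ik] - post.d_samples[:, il])


def or_matrix_from_d(d: np.ndarray) -> np.ndarray:
    """K x K odds-ratio matrix exp(d_k - d_l) from a point d vector."""
    d = np.asarray(d, dtype=float)
    return np.exp(d[:, None] - d[None, :])


# -- sampler ----------------------------------------------------------------

class _CBData:
    def __init__(self, net: NMANetwork, reference: str):
        self.K = net.n_treatments
        self.ref = net.treatment_index(reference)
        studies = net.study_ids
        self.I = len(studies)
        self.baseline_map: dict[str, str] = {}

        base_y, base_n, base_t = [], [], []
        nb_trial, nb_slot, nb_y, nb_n, nb_t = [], [], [], [], []
        row_count = []
        for i, sid in enumerate(studies):
            arms = sorted(net.arms_of(sid), key=lambda a: net.treatment_index(a.treatment_id))
            b = arms[0]
            self.baseline_map[sid] = b.treatment_id
            base_y.append(b.events)
            base_n.append(b.sample_size)
            base_t.append(net.treatment_index(b.treatment_id))
            row_count.append(len(arms) - 1)
            for j, arm in enumerate(arms[1:]):
                nb_trial.append(i)
                nb_slot.append(j)
                nb_y.append(arm.events)
                nb_n.append(arm.sample_size)
                nb_t.append(net.treatment_index(arm.treatment_id))
        self.base_y = np.array(base_y, dtype=float)
        self.base_n = np.array(base_n, dtype=float)
        self.base_t = np.array(base_t)
        self.row_count = np.array(row_count)
        self.M = int(self.row_count.max())
        self.nb_trial = np.array(nb_trial)
        self.nb_slot = np.array(nb_slot)
        self.nb_y = np.array(nb_y, dtype=float)
        self.nb_n = np.array(nb_n, dtype=float)
        self.nb_t = np.array(nb_t)
        self.n_nb = len(nb_y)

        # free-parameter columns (all treatments except the reference)
        free = [k for k in range(self.K) if k != self.ref]
        self.free = np.array(free)
        col = -np.ones(self.K, dtype=int)
        col[free] = np.arange(self.K - 1)
        self.col_plus = col[self.nb_t]                      # may be -1 (=ref)
        self.col_minus = col[self.base_t[self.nb_trial]]    # -1 when baseline=ref

        # T_i'1 per trial and the constant part of the Gibbs precision
        Kf = self.K - 1
        self.Tsum = np.zeros((self.I, Kf))
        M_mat = np.zeros((Kf, Kf))
        for i in range(self.I):
            sel = self.nb_trial == i
            m = int(self.row_count[i])
            T = np.zeros((m, Kf))
            rows = np.arange(m)
            cp = self.col_plus[sel]
            cm = self.col_minus[sel]
            T[rows[cp >= 0], cp[cp >= 0]] += 1.0
            T[rows[cm >= 0], cm[cm >= 0]] -= 1.0
            self.Tsum[i] = T.sum(axis=0)
            M_mat += 2.0 * (T.T @ T - np.outer(self.Tsum[i], self.Tsum[i]) / (m + 1.0))
        self.M_mat = M_mat

    def prior_mean(self, d_free: np.ndarray) -> np.ndarray:
        """delta prior means d_{b(i)k} = d_k - d_{b(i)} for the nonbase arms."""
        dk = np.where(self.col_plus >= 0, d_free[np.clip(self.col_plus, 0, None)], 0.0)
        db = np.where(self.col_minus >= 0, d_free[np.clip(self.col_minus, 0, None)], 0.0)
        return dk - db


def _init_state(data: _CBData, rng):
    crude_b = np.clip((data.base_y + 0.5) / (data.base_n + 1.0), 1e-4, 1 - 1e-4)
    mu = logit(crude_b)
    crude_nb = np.clip((data.nb_y + 0.5) / (data.nb_n + 1.0), 1e-4, 1 - 1e-4)
    delta_flat = logit(crude_nb) - mu[data.nb_trial]
    delta = np.zeros((data.I, data.M))
    delta[data.nb_trial, data.nb_slot] = delta_flat
    # crude initial d: average observed contrast per free treatment
    Kf = data.K - 1
    d_free = np.zeros(Kf)
    counts = np.zeros(Kf)
    sel = data.col_plus >= 0
    np.add.at(d_free, data.col_plus[sel], delta_flat[sel])
    np.add.at(counts, data.col_plus[sel], 1.0)
    d_free = np.where(counts > 0, d_free / np.maximum(counts, 1.0), 0.0)
    mu = mu + 0.05 * rng.standard_normal(data.I)
    return mu, delta, d_free


def _run_cb_chain(data: _CBData, priors: CBPriors, config: MCMCConfig, chain: int):
    rng = chain_rng(config, chain)
    I, Kf = data.I, data.K - 1
    mu, delta, d_free = _init_state(data, rng)
    sigma = float(
        np.clip(0.2 * (1 + 0.1 * rng.standard_normal()),
                0.02 * priors.sigma_max, 0.8 * priors.sigma_max)
    )

    ad_delta = ScaleAdapter(I, 0.4)
    ad_mu = ScaleAdapter(I, 0.3)
    ad_sig = ScaleAdapter((), 0.2)

    ti, si = data.nb_trial, data.nb_slot
    mu_var = priors.mu_sd ** 2

    def nb_loglik(mu_, delta_):
        p = expit(mu_[ti] + delta_[ti, si])
        return binom_loglik(data.nb_y, data.nb_n, p)

    def base_loglik(mu_):
        return binom_loglik(data.base_y, data.base_n, expit(mu_))

    def delta_prior(delta_, d_free_, sigma_):
        resid = np.zeros_like(delta_)
        resid[ti, si] = delta_[ti, si] - data.prior_mean(d_free_)
        return half_exch_cov_logpdf(resid, data.row_count, sigma_)

    ll_nb = nb_loglik(mu, delta)
    ll_nb_trial = np.bincount(ti, weights=ll_nb, minlength=I)
    ll_base = base_loglik(mu)
    pri_delta = delta_prior(delta, d_free, sigma)

    n_warm = config.n_adapt + config.n_burnin
    total = n_warm + config.n_iter
    kept = config.n_iter // config.thin
    d_out = np.empty((kept, Kf))
    sig_out = np.empty(kept)
    mu_out = np.empty((kept, I))
    kidx = 0

    eye = np.eye(Kf)
    for it in range(total):
        adapting = it < config.n_adapt

        # contrast vectors, one vector proposal per trial
        prop = delta.copy()
        prop[ti, si] += ad_delta.scale[ti] * rng.standard_normal(data.n_nb)
        ll_new = nb_loglik(mu, prop)
        ll_new_trial = np.bincount(ti, weights=ll_new, minlength=I)
        pri_new = delta_prior(prop, d_free, sigma)
        acc = np.log(rng.random(I)) < (pri_new - pri_delta) + (ll_new_trial - ll_nb_trial)
        if np.any(acc):
            delta[acc] = prop[acc]
            pri_delta = np.where(acc, pri_new, pri_delta)
            ll_nb_trial = np.where(acc, ll_new_trial, ll_nb_trial)
            ll_nb = np.where(acc[ti], ll_new, ll_nb)
        if adapting:
            ad_delta.update(acc.astype(float))

        # trial baselines (conditionally independent across trials)
        prop_mu = mu + ad_mu.scale * rng.standard_normal(I)
        ll_new = nb_loglik(prop_mu, delta)
        ll_new_trial = np.bincount(ti, weights=ll_new, minlength=I)
        ll_base_new = base_loglik(prop_mu)
        dlp = (ll_new_trial - ll_nb_trial) + (ll_base_new - ll_base)
        dlp += -0.5 * (prop_mu**2 - mu**2) / mu_var
        acc = np.log(rng.random(I)) < dlp
        if np.any(acc):
            mu = np.where(acc, prop_mu, mu)
            ll_base = np.where(acc, ll_base_new, ll_base)
            ll_nb_trial = np.where(acc, ll_new_trial, ll_nb_trial)
            ll_nb = np.where(acc[ti], ll_new, ll_nb)
        if adapting:
            ad_mu.update(acc.astype(float))

        # basic parameters: exact Gibbs (Gaussian conditional)
        sig2 = sigma * sigma
        delta_flat = delta[ti, si]
        s_per_trial = np.bincount(ti, weights=delta_flat, minlength=I)
        b_vec = np.zeros(Kf)
        selp = data.col_plus >= 0
        selm = data.col_minus >= 0
        np.add.at(b_vec, data.col_plus[selp], delta_flat[selp])
        np.add.at(b_vec, data.col_minus[selm], -delta_flat[selm])
        b_vec -= ((s_per_trial / (data.row_count + 1.0))[:, None] * data.Tsum).sum(axis=0)
        b_vec *= 2.0 / sig2
        A = eye / priors.d_sd**2 + data.M_mat / sig2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b_vec)
        z = rng.standard_normal(Kf)
        d_free = mean + np.linalg.solve(L.T, z)
        pri_delta = delta_prior(delta, d_free, sigma)

        # heterogeneity SD
        prop_s = sigma + ad_sig.scale * rng.standard_normal()
        if 0.0 < prop_s < priors.sigma_max:
            pri_new = delta_prior(delta, d_free, prop_s)
            if np.log(rng.random()) < pri_new.sum() - pri_delta.sum():
                sigma = float(prop_s)
                pri_delta = pri_new
                acc_s = 1.0
            else:
                acc_s = 0.0
        else:
            acc_s = 0.0
        if adapting:
            ad_sig.update(acc_s)

        if it >= n_warm and (it - n_warm) % config.thin == 0 and kidx < kept:
            d_out[kidx] = d_free
            sig_out[kidx] = sigma
            mu_out[kidx] = mu
            kidx += 1

    return d_out[:kidx], sig_out[:kidx], mu_out[:kidx]


def fit_cb(
    net: NMANetwork,
    config: MCMCConfig,
    priors: CBPriors | None = None,
    reference: str | None = None,
) -> CBPosterior:
    """Fit the CB model by MCMC and return pooled posterior draws.

    ``reference`` defaults to the first treatment in network order; the
    reference column of ``d_samples`` is identically zero.
    """
    priors = priors or CBPriors()
    reference = reference if reference is not None else net.treatments[0]
    if reference not in net.treatments:
        raise KeyError(f"reference treatment {reference!r} not in network")
    if not nx.is_connected(comparison_graph(net)):
        raise ValueError(f"network {net.name!r} is disconnected; cannot fit NMA")
    data = _CBData(net, reference)

    d_ch, sig_ch, mu_ch = [], [], []
    for c in range(config.n_chains):
        d_s, sig_s, mu_s = _run_cb_chain(data, priors, config, c)
        d_ch.append(d_s)
        sig_ch.append(sig_s)
        mu_ch.append(mu_s)
    d_arr = np.stack(d_ch)       # (chains, draws, K-1)
    sig_arr = np.stack(sig_ch)
    mu_arr = np.stack(mu_ch)

    rhat = compute_rhat({"d": d_arr, "sigma": sig_arr})
    warns = convergence_warnings(rhat, config.rhat_threshold)

    # expand d to a full K-column matrix with the reference column at zero
    draws = d_arr.reshape(-1, data.K - 1)
    full = np.zeros((draws.shape[0], data.K))
    full[:, data.free] = draws
    return CBPosterior(
        treatments=net.treatments,
        reference=reference,
        d_samples=full,
        sigma_samples=sig_arr.ravel(),
        baseline_samples=mu_arr.reshape(-1, data.I),
        baseline_map=data.baseline_map,
        rhat=rhat,
        warnings=warns,
    )


def cb_summary(post: CBPosterior, level: float = 0.95) -> dict:
    """JSON-ready OR table (posterior medians and CrIs) for all pairs."""
    lo = (1.0 - level) / 2.0
    table = []
    K = len(post.treatments)
    for a in range(K):
        for b in range(a + 1, K):
            ors = np.exp(post.d_samples[:, a] - post.d_samples[:, b])
            qlo, med, qhi = np.quantile(ors, [lo, 0.5, 1.0 - lo])
            table.append(
                {
                    "pair": [post.treatments[a], post.treatments[b]],
                    "or_median": float(med),
                    "or_ci": [float(qlo), float(qhi)],
                }
            )
    return {
        "treatments": list(post.treatments),
        "reference": post.reference,
        "sigma_median": float(np.median(post.sigma_samples)),
        "or_table": table,
        "rhat": {k: v for k, v in post.rhat.items() if "[" not in k},
        "warnings": list(post.warnings),
    }
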