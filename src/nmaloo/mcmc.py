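"""Shared MCMC machinery: configuration, adaptive random-walk scales,
closed forms for exchangeable covariance structures, convergence
diagnostics and deterministic seed derivation.

Both NMA models are sampled with adaptive Metropolis-within-Gibbs: latent
blocks are updated with vectorized random-walk proposals whose scales adapt
toward standard acceptance targets during warm-up and are frozen afterwards.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

#: Robbins-Monro acceptance target for coordinate-wise random walks
ACCEPT_TARGET = 0.44
ADAPT_BATCH = 50


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults are a production profile (3 chains, long warm-up); tests use
    :meth:`test_profile`.  ``n_adapt`` iterations adapt proposal scales,
    ``n_burnin`` more are discarded with scales frozen, then ``n_iter``
    draws are kept (after thinning by ``thin``).  Gelman-Rubin split-R̂ is
    computed per parameter; any value above ``rhat_threshold`` attaches a
    convergence warning to the posterior.
    """

    n_chains: int = 3
    n_adapt: int = 5_000
    n_burnin: int = 20_000
    n_iter: int = 50_000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("Gelman-Rubin diagnostics require n_chains >= 2")
        for name in ("n_adapt", "n_burnin", "n_iter", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def test_profile(cls, seed: int = 0, **kw) -> "MCMCConfig":
        """Small profile for unit tests and quick exploration."""
        defaults = dict(
            n_chains=2, n_adapt=800, n_burnin=700, n_iter=2500, thin=1, seed=seed
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin


def derive_seed(base_seed: int, *tokens: object) -> int:
    """Deterministic child seed from a base seed and arbitrary labels.

    CRC32 over the token repr keeps streams stable when networks or studies
    are added elsewhere in a run.
    """
    h = zlib.crc32(repr(tokens).encode())
    return int((np.uint64(base_seed) * np.uint64(2654435761) + np.uint64(h)) % (2**31))


def chain_rng(config: MCMCConfig, chain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, chain]))


class ScaleAdapter:
    """Robbins-Monro adaptation of a vector of proposal scales."""

    def __init__(self, shape, initial: float = 0.5):
        self.log_scale = np.full(shape, np.log(initial))
        self.accepts = np.zeros(shape)
        self.count = 0
        self.batch = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.accepts += accepted
        self.count += 1
        if self.count >= ADAPT_BATCH:
            self.batch += 1
            rate = self.accepts / self.count
            step = 1.0 / np.sqrt(self.batch)
            self.log_scale += step * (rate - ACCEPT_TARGET)
            self.log_scale = np.clip(self.log_scale, -8.0, 3.0)
            self.accepts[...] = 0.0
            self.count = 0


# -- exchangeable-structure closed forms -----------------------------------

def exch_corr_logpdf(u: np.ndarray, row_count: np.ndarray, rho: float) -> np.ndarray:
    """Row-wise log density of MVN(0, R_m(rho)) with exchangeable correlation.

    ``u`` is a padded (I, A) matrix (zeros outside each row's ``row_count``
    entries); R_m = (1-rho) I + rho J.  Uses the rank-one closed forms for
    the inverse and determinant, so no per-trial factorization is needed.
    """
    m = row_count.astype(float)
    s = u.sum(axis=1)
    ss = (u * u).sum(axis=1)
    denom = 1.0 + (m - 1.0) * rho
    quad = (ss - rho * s * s / denom) / (1.0 - rho)
    logdet = (m - 1.0) * np.log1p(-rho) + np.log(denom)
    return -0.5 * (quad + logdet + m * np.log(2.0 * np.pi))


def half_exch_cov_logpdf(u: np.ndarray, row_count: np.ndarray, sigma: float) -> np.ndarray:
    """Row-wise log density of MVN(0, sigma^2 P_m), P_m = (I + J)/2.

    This is the homogeneous-variance structure with correlation 1/2 used for
    multi-arm contrast vectors: var sigma^2, cov sigma^2/2.
    P^{-1} = 2(I - J/(m+1)), det P = (m+1)/2^m.
    """
    m = row_count.astype(float)
    s = u.sum(axis=1)
    ss = (u * u).sum(axis=1)
    sig2 = sigma * sigma
    quad = (2.0 / sig2) * (ss - s * s / (m + 1.0))
    logdet = m * np.log(sig2) + np.log(m + 1.0) - m * np.log(2.0)
    return -0.5 * (quad + logdet + m * np.log(2.0 * np.pi))


# -- diagnostics -----------------------------------------------------------

def compute_rhat(samples: dict[str, np.ndarray]) -> dict[str, float]:
    """Split-R̂ per parameter.

    ``samples`` maps a name to an array of shape (chains, draws) or
    (chains, draws, dim); vector parameters report the worst component as
    ``name`` plus per-component entries ``name[j]``.
    """
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.from_dict(posterior=samples))
    for name, arr in samples.items():
        vals = np.atleast_1d(np.asarray(ds[name]))
        if arr.ndim == 2:
            out[name] = float(vals.ravel()[0])
        else:
            for j, v in enumerate(vals.ravel()):
                out[f"{name}[{j}]"] = float(v)
            out[name] = float(np.nanmax(vals))
    return out


def convergence_warnings(rhat: dict[str, float], threshold: float) -> tuple[str, ...]:
    flagged = {k: v for k, v in rhat.items() if "[" not in k and v > threshold}
    return tuple(
        f"R-hat {v:.3f} for {k} exceeds {threshold}" for k, v in sorted(flagged.items())
    )


def binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Elementwise binomial log likelihood (without the constant term)."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return y * np.log(p) + (n - y) * np.log1p(-p)
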