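"""Synthetic NMA networks with the statistical structure the analysis assumes.

The generator emulates the geometry of published binary-outcome NMA
collections (4-12 treatments, roughly 9-110 trials, treatment frequencies
from 2 upward, mostly incomplete networks) and simulates outcomes under
either generative model the pipeline fits:

* arm-based truth: probit-linked arm probabilities with exchangeable
  correlated trial random effects, and
* contrast-based truth: trial baselines on the logit scale plus contrast
  vectors with variance sigma^2 and pairwise covariance sigma^2/2.

All generators are pure functions of (spec, seed).  Default per-arm sample
sizes are log-uniform on [20, 400]: small-to-moderate trials are exactly the
regime where excluding a single trial moves the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit, ndtr

from .network_data import ArmRecord, NMANetwork, validate_inclusion

SizeDist = tuple[float, float] | int | Callable[[np.random.Generator, int], np.ndarray]

DEFAULT_ARM_SIZES: Mapping[int, float] = {2: 0.8, 3: 0.2}
DEFAULT_PER_ARM_N: SizeDist = (20.0, 400.0)


def _draw_per_arm_n(dist: SizeDist, rng: np.random.Generator, size: int) -> np.ndarray:
    if callable(dist):
        return np.asarray(dist(rng, size), dtype=int)
    if isinstance(dist, int):
        return np.full(size, dist, dtype=int)
    lo, hi = dist
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size)).astype(int)


@dataclass(frozen=True)
class DesignSpec:
    """Geometry of a synthetic network: K treatments, I trials, the
    distribution of arms per trial and of per-arm sample sizes."""

    n_treatments: int
    n_trials: int
    arm_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_SIZES)
    )
    treatment_assignment: str = "uniform"  # or "frequency_weighted"
    per_arm_n: SizeDist = DEFAULT_PER_ARM_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 2 or self.n_trials < 1:
            raise ValueError("need K >= 2 treatments and I >= 1 trials")
        sizes = list(self.arm_size_distribution)
        if any(s < 2 or s > self.n_treatments for s in sizes):
            raise ValueError("arm sizes must lie in [2, K]")
        if self.treatment_assignment not in ("uniform", "frequency_weighted"):
            raise ValueError("unknown treatment_assignment")


@dataclass(frozen=True)
class ABTruth:
    """Arm-based generative truth: probit effects mu (length K),
    random-effect SD sigma, exchangeable correlation rho."""

    mu: tuple[float, ...]
    sigma: float
    rho: float

    def __post_init__(self) -> None:
        K = len(self.mu)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (-1.0 / (K - 1) < self.rho < 1.0):
            raise ValueError(
                f"rho must lie in (-1/(K-1), 1) = ({-1.0/(K-1):.3f}, 1) "
                "for a positive-definite correlation matrix"
            )

    def marginal_rates(self) -> np.ndarray:
        """Closed-form population-averaged rates Phi(mu/sqrt(1+sigma^2))."""
        mu = np.asarray(self.mu)
        return ndtr(mu / np.sqrt(1.0 + self.sigma**2))


@dataclass(frozen=True)
class CBTruth:
    """Contrast-based truth: baseline distribution (normal, logit scale),
    basic parameters d versus the reference (first treatment), SD sigma."""

    baseline_mean: float
    baseline_sd: float
    d: tuple[float, ...]  # length K-1, treatments 2..K vs treatment 1
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.baseline_sd < 0:
            raise ValueError("sigma and baseline_sd must be >= 0")

    def d_full(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.d, dtype=float)])

    def true_or(self, k: int, l: int) -> float:
        """Implied OR between treatments k and l (0-based indices)."""
        d = self.d_full()
        return float(np.exp(d[k] - d[l]))


def _labels(K: int) -> list[str]:
    return [f"T{k+1}" for k in range(K)]


def sample_design(spec: DesignSpec) -> list[tuple[int, ...]]:
    """Sample per-trial treatment sets (0-based indices).

    Guarantees: each trial has >= 2 distinct treatments, every treatment
    appears in >= 2 trials, and the co-occurrence graph is connected.
    Deterministic given ``spec.seed``.  Raises on infeasible geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    K, I = spec.n_treatments, spec.n_trials
    sizes_support = np.array(sorted(spec.arm_size_distribution))
    probs = np.array([spec.arm_size_distribution[s] for s in sizes_support], float)
    probs /= probs.sum()

    max_size = int(sizes_support.max())
    if I < 2 or I * max_size < 2 * K:
        raise ValueError(
            f"infeasible design: cannot give {K} treatments frequency >= 2 "
            f"in {I} trials with at most {max_size} arms each"
        )

    for attempt in range(60):
        m = rng.choice(sizes_support, size=I, p=probs)
        # bump sizes (within the declared support) until there are enough
        # slots for every treatment twice
        while m.sum() < 2 * K:
            i = int(rng.integers(I))
            if m[i] < max_size:
                m[i] += 1
        design = [set() for _ in range(I)]
        # deal two copies of every treatment into distinct trials first
        tokens = np.repeat(np.arange(K), 2)
        rng.shuffle(tokens)
        order = rng.permutation(I)
        ok = True
        for tok in tokens:
            placed = False
            for i in order:
                if len(design[i]) < m[i] and tok not in design[i]:
                    design[i].add(int(tok))
                    placed = True
                    break
            order = rng.permutation(I)
            if not placed:
                ok = False
                break
        if not ok:
            continue
        # fill remaining slots
        counts = np.bincount(
            np.concatenate([list(s) for s in design]).astype(int), minlength=K
        ).astype(float)
        for i in range(I):
            while len(design[i]) < m[i]:
                avail = np.array([k for k in range(K) if k not in design[i]])
                if avail.size == 0:
                    break
                if spec.treatment_assignment == "frequency_weighted":
                    w = counts[avail] + 1.0
                    w /= w.sum()
                    k = int(rng.choice(avail, p=w))
                else:
                    k = int(rng.choice(avail))
                design[i].add(k)
                counts[k] += 1
        freq = np.zeros(K, dtype=int)
        for s in design:
            freq[list(s)] += 1
        if freq.min() < 2:
            continue
        if _connected(design, K):
            return [tuple(sorted(s)) for s in design]
    raise ValueError("could not sample a connected design satisfying frequency >= 2")


def _connected(design: Sequence[set[int] | tuple[int, ...]], K: int) -> bool:
    adj = [set() for _ in range(K)]
    for s in design:
        s = list(s)
        for a in s:
            for b in s:
                if a != b:
                    adj[a].add(b)
    seen = {0}
    stack = [0]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return len(seen) == K


def _exch_chol(m: int, rho: float) -> np.ndarray:
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


def simulate_ab(
    design: Sequence[tuple[int, ...]],
    truth: ABTruth,
    per_arm_n: SizeDist = DEFAULT_PER_ARM_N,
    seed: int = 0,
    name: str = "ab-synthetic",
    outcome_direction: str = "beneficial",
) -> NMANetwork:
    """Simulate binary outcomes under the arm-based generative model.

    For each trial the correlated probit random-effect vector is drawn for
    the trial's own treatment set (the marginal of the exchangeable MVN),
    arm probabilities are Phi(mu_k + sigma v_ik), and events are binomial.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB]))
    K = len(truth.mu)
    if any(k >= K for s in design for k in s):
        raise ValueError("design references a treatment outside the truth")
    labels = _labels(K)
    mu = np.asarray(truth.mu)
    arms: list[ArmRecord] = []
    for i, s in enumerate(design):
        m = len(s)
        L = _exch_chol(m, truth.rho)
        v = L @ rng.standard_normal(m)
        ns = _draw_per_arm_n(per_arm_n, rng, m)
        p = ndtr(mu[list(s)] + truth.sigma * v)
        ys = rng.binomial(ns, p)
        for k, n_k, y_k in zip(s, ns, ys):
            arms.append(ArmRecord(f"S{i+1}", labels[k], int(y_k), int(n_k)))
    present = sorted({k for s in design for k in s})
    return NMANetwork(
        tuple(labels[k] for k in present), tuple(arms), outcome_direction, name
    )


def simulate_cb(
    design: Sequence[tuple[int, ...]],
    truth: CBTruth,
    per_arm_n: SizeDist = DEFAULT_PER_ARM_N,
    seed: int = 0,
    name: str = "cb-synthetic",
    outcome_direction: str = "beneficial",
) -> NMANetwork:
    """Simulate binary outcomes under the contrast-based generative model.

    Per trial: baseline mu_i ~ N(baseline_mean, baseline_sd^2) on the logit
    scale; the contrast vector versus the trial baseline (lowest-indexed
    treatment) is MVN with mean d_{b(i)k}, variance sigma^2 and pairwise
    covariance sigma^2/2; arm probabilities are expit(mu_i + delta).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCB]))
    K = len(truth.d) + 1
    if any(k >= K for s in design for k in s):
        raise ValueError("design references a treatment outside the truth")
    labels = _labels(K)
    d = truth.d_full()
    arms: list[ArmRecord] = []
    for i, s in enumerate(design):
        s = tuple(sorted(s))
        b = s[0]
        others = s[1:]
        m = len(others)
        mu_i = rng.normal(truth.baseline_mean, truth.baseline_sd)
        ns = _draw_per_arm_n(per_arm_n, rng, m + 1)
        if m:
            L = _exch_chol(m, 0.5) if m > 1 else np.ones((1, 1))
            delta = d[list(others)] - d[b] + truth.sigma * (L @ rng.standard_normal(m))
        else:
            delta = np.zeros(0)
        p = np.concatenate([[expit(mu_i)], expit(mu_i + delta)])
        ys = rng.binomial(ns, p)
        for k, n_k, y_k in zip((b, *others), ns, ys):
            arms.append(ArmRecord(f"S{i+1}", labels[k], int(y_k), int(n_k)))
    present = sorted({k for s in design for k in s})
    return NMANetwork(
        tuple(labels[k] for k in present), tuple(arms), outcome_direction, name
    )


# -- benchmark suite --------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkNetwork:
    """A synthetic network with its generative truth for recovery tests."""

    network: NMANetwork
    model: str  # "ab" or "cb"
    truth: ABTruth | CBTruth
    design: tuple[tuple[int, ...], ...]


def _force_min_frequency_two(
    design: list[tuple[int, ...]], K: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Prune the last treatment down to exactly two trials (repairing the
    geometry so the result stays connected and valid)."""
    rare = K - 1
    holding = [i for i, s in enumerate(design) if rare in s]
    keep = set(holding[:2])
    out = []
    for i, s in enumerate(design):
        if rare in s and i not in keep:
            s = tuple(x for x in s if x != rare)
            if len(s) < 2:
                extra = int(rng.choice([k for k in range(K - 1) if k not in s]))
                s = tuple(sorted((*s, extra)))
        out.append(tuple(sorted(s)))
    if not _connected(out, K):  # pragma: no cover - repair is rarely needed
        out[min(keep)] = tuple(sorted(set(out[min(keep)]) | {0}))
    return out


def make_benchmark_suite(seed: int = 0) -> list[BenchmarkNetwork]:
    """A fixed small suite of synthetic networks with known truths.

    Contains AB- and CB-generated members spanning 4-6 treatments and 9-24
    trials, including one network with a treatment at the minimum allowed
    frequency of two trials.  Regenerates identically from the same seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB5]))
    suite: list[BenchmarkNetwork] = []

    spec1 = DesignSpec(n_treatments=4, n_trials=9, arm_size_distribution={2: 1.0}, seed=seed)
    design1 = sample_design(spec1)
    truth1 = ABTruth(mu=(-0.2, 0.1, 0.3, -0.4), sigma=0.3, rho=0.5)
    suite.append(
        BenchmarkNetwork(
            simulate_ab(design1, truth1, seed=seed, name="bench-ab-small"),
            "ab", truth1, tuple(design1),
        )
    )

    spec2 = DesignSpec(n_treatments=5, n_trials=16, seed=seed + 1)
    design2 = _force_min_frequency_two(sample_design(spec2), 5, rng)
    truth2 = ABTruth(mu=(0.0, 0.2, -0.3, 0.4, -0.1), sigma=0.25, rho=0.4)
    suite.append(
        BenchmarkNetwork(
            simulate_ab(design2, truth2, seed=seed + 1, name="bench-ab-rare"),
            "ab", truth2, tuple(design2),
        )
    )

    spec3 = DesignSpec(n_treatments=4, n_trials=12, seed=seed + 2)
    design3 = sample_design(spec3)
    truth3 = CBTruth(baseline_mean=-0.5, baseline_sd=0.4, d=(0.5, -0.3, 0.2), sigma=0.2)
    suite.append(
        BenchmarkNetwork(
            simulate_cb(design3, truth3, seed=seed + 2, name="bench-cb"),
            "cb", truth3, tuple(design3),
        )
    )

    spec4 = DesignSpec(
        n_treatments=6, n_trials=24, arm_size_distribution={2: 0.7, 3: 0.3}, seed=seed + 3
    )
    design4 = sample_design(spec4)
    truth4 = ABTruth(mu=(-0.6, -0.3, 0.0, 0.2, 0.4, -0.1), sigma=0.35, rho=0.3)
    suite.append(
        BenchmarkNetwork(
            simulate_ab(design4, truth4, seed=seed + 3, name="bench-ab-wide"),
            "ab", truth4, tuple(design4),
        )
    )

    for entry in suite:
        report = validate_inclusion(entry.network)
        assert report.passed, f"benchmark {entry.network.name} violates inclusion"
    return suite


def write_truth_sidecar(truth: ABTruth | CBTruth, path: str | Path) -> None:
    """Persist a generative truth next to a network file (YAML)."""
    path = Path(path)
    if isinstance(truth, ABTruth):
        payload = {"model": "ab", "mu": list(truth.mu), "sigma": truth.sigma, "rho": truth.rho}
    else:
        payload = {
            "model": "cb",
            "baseline_mean": truth.baseline_mean,
            "baseline_sd": truth.baseline_sd,
            "d": list(truth.d),
            "sigma": truth.sigma,
        }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
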