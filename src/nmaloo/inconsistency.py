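"""Discrepancy-factor inconsistency detection under the arm-based framework.

To assess evidence consistency between two treatments k1 and k2, trials are
partitioned into four groups: (i) trials containing both, (ii) trials with
k1 but not k2, (iii) trials with k2 but not k1, and (iv) the rest.  A pair
is eligible only when groups (i), (ii) and (iii) are all non-empty.  Fitting
the arm-based model with group-specific fixed effects for k1 and k2 yields
the posterior of the discrepancy factor::

    Delta = (mu_k1^(i) - mu_k2^(i)) - (mu_k1^(ii) - mu_k2^(iii)),

the gap between the direct (within-group-(i)) and indirect contrast on the
probit scale.  Inconsistency is flagged when zero falls outside the central
credible interval at the configured level.  Each pair needs its own model
fit; group (iv) trials stay in the model (they inform the shared sigma, rho
and the other treatments' effects) but carry no group-specific parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ab_model import ABPriors, fit_ab
from .mcmc import MCMCConfig
from .network_data import ArmRecord, NMANetwork


@dataclass(frozen=True)
class TrialPartition:
    pair: tuple[str, str]
    group_both: tuple[str, ...]
    group_k1_only: tuple[str, ...]
    group_k2_only: tuple[str, ...]
    group_neither: tuple[str, ...]

    @property
    def eligible(self) -> bool:
        return bool(self.group_both and self.group_k1_only and self.group_k2_only)

    def empty_groups(self) -> list[str]:
        names = []
        if not self.group_both:
            names.append("both (i)")
        if not self.group_k1_only:
            names.append("k1-only (ii)")
        if not self.group_k2_only:
            names.append("k2-only (iii)")
        return names


@dataclass(frozen=True)
class DiscrepancyResult:
    pair: tuple[str, str]
    delta_samples: np.ndarray
    credible_interval: tuple[float, float]
    level: float
    inconsistent: bool
    rhat: dict[str, float]
    warnings: tuple[str, ...] = ()


def partition_trials(net: NMANetwork, k1: str, k2: str) -> TrialPartition:
    """Four-way partition of trials by membership of k1 and k2."""
    if k1 == k2:
        raise ValueError("treatments must differ")
    for t in (k1, k2):
        if t not in net.treatments:
            raise KeyError(f"unknown treatment {t!r}")
    both, only1, only2, neither = [], [], [], []
    for sid in net.study_ids:
        s = set(net.study_treatments(sid))
        if k1 in s and k2 in s:
            both.append(sid)
        elif k1 in s:
            only1.append(sid)
        elif k2 in s:
            only2.append(sid)
        else:
            neither.append(sid)
    return TrialPartition((k1, k2), tuple(both), tuple(only1), tuple(only2), tuple(neither))


def eligible_pairs(net: NMANetwork) -> list[tuple[str, str]]:
    """All unordered treatment pairs with non-empty groups (i), (ii), (iii)."""
    return [
        (a, b)
        for a, b in combinations(net.treatments, 2)
        if partition_trials(net, a, b).eligible
    ]


def _augmented_network(net: NMANetwork, part: TrialPartition) -> tuple[NMANetwork, dict[str, str]]:
    """Rename k1/k2 arms by evidence group so the AB fit estimates separate
    fixed effects per group; returns the network and the label map."""
    k1, k2 = part.pair
    in_both = set(part.group_both)
    labels = {
        "k1_direct": f"{k1}(i)",
        "k2_direct": f"{k2}(i)",
        "k1_indirect": f"{k1}(ii)",
        "k2_indirect": f"{k2}(iii)",
    }
    arms = []
    order: list[str] = []
    for arm in net.arms:
        t = arm.treatment_id
        if t == k1:
            t = labels["k1_direct"] if arm.study_id in in_both else labels["k1_indirect"]
        elif t == k2:
            t = labels["k2_direct"] if arm.study_id in in_both else labels["k2_indirect"]
        arms.append(ArmRecord(arm.study_id, t, arm.events, arm.sample_size))
        if t not in order:
            order.append(t)
    aug = NMANetwork(tuple(order), tuple(arms), net.outcome_direction, f"{net.name}:aug")
    return aug, labels


def fit_discrepancy(
    net: NMANetwork,
    k1: str,
    k2: str,
    config: MCMCConfig,
    level: float = 0.95,
    priors: ABPriors | None = None,
) -> DiscrepancyResult:
    """Posterior of the discrepancy factor for one treatment pair.

    Raises on an ineligible pair, naming the empty evidence group(s).
    """
    part = partition_trials(net, k1, k2)
    if not part.eligible:
        raise ValueError(
            f"pair ({k1}, {k2}) ineligible for inconsistency detection: "
            f"empty group(s) {', '.join(part.empty_groups())}"
        )
    aug, labels = _augmented_network(net, part)
    post = fit_ab(aug, config, priors, check_connected=False)
    idx = {name: post.treatments.index(lbl) for name, lbl in labels.items()}
    mu = post.mu_samples
    delta = (mu[:, idx["k1_direct"]] - mu[:, idx["k2_direct"]]) - (
        mu[:, idx["k1_indirect"]] - mu[:, idx["k2_indirect"]]
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(delta, [alpha, 1.0 - alpha])
    return DiscrepancyResult(
        pair=(k1, k2),
        delta_samples=delta,
        credible_interval=(float(lo), float(hi)),
        level=level,
        inconsistent=not (lo <= 0.0 <= hi),
        rhat=post.rhat,
        warnings=post.warnings,
    )


def discrepancy_summary(res: DiscrepancyResult, part: TrialPartition | None = None) -> dict:
    out = {
        "pair": list(res.pair),
        "level": res.level,
        "credible_interval": list(res.credible_interval),
        "inconsistent": bool(res.inconsistent),
        "delta_mean": float(res.delta_samples.mean()),
        "warnings": list(res.warnings),
    }
    if part is not None:
        out["group_sizes"] = {
            "both": len(part.group_both),
            "k1_only": len(part.group_k1_only),
            "k2_only": len(part.group_k2_only),
            "neither": len(part.group_neither),
        }
    return out
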