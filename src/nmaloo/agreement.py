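"""Agreement between the arm-based and contrast-based impact metrics.

Cells are the aligned (network, exclusion, treatment-pair) log-OR changes
from the two approaches.  Three views are provided:

* scatter data around the identity line with a deviation flag per cell,
* Bland-Altman limits of agreement on the differences AB - CB, and
* a network-level bootstrap comparing eta_AB and eta_CB, the means of the
  absolute log-OR changes pooled over every cell, with percentile CIs and a
  two-sided p-value computed under a recentered null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loo import LOOResult

#: default |ab - cb| threshold for flagging a scatter cell as off-identity
DEVIATION_THRESHOLD = 0.1


@dataclass(frozen=True)
class PairedChanges:
    """Aligned per-cell (ab, cb) log-OR changes, grouped by network."""

    network_ids: tuple[str, ...]
    ab: tuple[np.ndarray, ...]   # one flat array per network
    cb: tuple[np.ndarray, ...]
    labels: tuple[tuple[tuple[str, str, str], ...], ...]  # (study, k, l) per cell

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.ab), np.concatenate(self.cb)

    @property
    def n_networks(self) -> int:
        return len(self.network_ids)


def collect_paired_changes(results: list[LOOResult]) -> PairedChanges:
    """Extract aligned upper-triangle log-OR changes from LOO results."""
    ids, abs_, cbs, labels = [], [], [], []
    for res in results:
        K = res.network.n_treatments
        iu = np.triu_indices(K, k=1)
        ab_cells, cb_cells, cell_labels = [], [], []
        for rec in res.eligible_records():
            ab_cells.append(rec.ab_logor_changes[iu])
            cb_cells.append(rec.cb_logor_changes[iu])
            for a, b in zip(*iu):
                cell_labels.append(
                    (rec.excluded_study, res.network.treatments[a], res.network.treatments[b])
                )
        ids.append(res.network.name)
        abs_.append(np.concatenate(ab_cells) if ab_cells else np.zeros(0))
        cbs.append(np.concatenate(cb_cells) if cb_cells else np.zeros(0))
        labels.append(tuple(cell_labels))
    return PairedChanges(tuple(ids), tuple(abs_), tuple(cbs), tuple(labels))


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    pct_within_limits: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Limits-of-agreement statistics for paired measurements.

    Differences are x - y; limits are mean +/- 1.96 * sample SD (n-1
    denominator); the within-limits proportion uses the closed interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least two paired values")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean, sd, (lo, hi), within, int(d.size))


@dataclass(frozen=True)
class EtaTest:
    """Bootstrap inference on eta_AB and eta_CB (mean absolute log-OR
    change, every cell weighted equally)."""

    eta_ab: float
    eta_cb: float
    ci_ab: tuple[float, float]
    ci_cb: tuple[float, float]
    p_value: float
    n_cells: int
    n_networks: int
    n_boot: int


def bootstrap_eta_test(
    changes: PairedChanges, B: int = 10_000, seed: int = 0
) -> EtaTest:
    """Network-level bootstrap for H0: eta_AB = eta_CB.

    Whole networks are resampled with replacement B times; percentile CIs
    come from the pooled means of |change| per resample.  The two-sided
    p-value uses a second bootstrap in which the per-cell differences
    |ab| - |cb| are recentered by their grand mean before resampling; p is
    the proportion of bootstrap statistics at least as extreme as the
    observed mean difference.
    """
    if changes.n_networks < 2:
        raise ValueError("bootstrap requires at least two networks")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    N = changes.n_networks
    # canonical network order so results do not depend on input ordering
    order = sorted(range(N), key=lambda i: changes.network_ids[i])
    abs_ab = [np.abs(changes.ab[i]) for i in order]
    abs_cb = [np.abs(changes.cb[i]) for i in order]
    pooled_ab = np.concatenate(abs_ab)
    pooled_cb = np.concatenate(abs_cb)
    eta_ab = float(pooled_ab.mean())
    eta_cb = float(pooled_cb.mean())

    sums_ab = np.array([a.sum() for a in abs_ab])
    sums_cb = np.array([c.sum() for c in abs_cb])
    counts = np.array([a.size for a in abs_ab], dtype=float)

    idx = rng.integers(N, size=(B, N))
    tot = counts[idx].sum(axis=1)
    boot_ab = sums_ab[idx].sum(axis=1) / tot
    boot_cb = sums_cb[idx].sum(axis=1) / tot
    ci_ab = tuple(float(q) for q in np.quantile(boot_ab, [0.025, 0.975]))
    ci_cb = tuple(float(q) for q in np.quantile(boot_cb, [0.025, 0.975]))

    # null bootstrap on recentered per-cell differences
    diffs = [a - c for a, c in zip(abs_ab, abs_cb)]
    observed = float(np.concatenate(diffs).mean())
    centered = [d - observed for d in diffs]
    sums_d = np.array([d.sum() for d in centered])
    idx0 = rng.integers(N, size=(B, N))
    tot0 = counts[idx0].sum(axis=1)
    boot_stat = sums_d[idx0].sum(axis=1) / tot0
    p = float(np.mean(np.abs(boot_stat) >= abs(observed)))
    return EtaTest(
        eta_ab=eta_ab,
        eta_cb=eta_cb,
        ci_ab=ci_ab,
        ci_cb=ci_cb,
        p_value=p,
        n_cells=int(pooled_ab.size),
        n_networks=N,
        n_boot=B,
    )


def scatter_data(
    changes: PairedChanges, deviation_threshold: float = DEVIATION_THRESHOLD
) -> pd.DataFrame:
    """Plot-ready table of (ab, cb) cells with off-identity deviation flags.

    Columns: network, study, pair, ab, cb, deviation, flagged.
    """
    if changes.n_networks == 0 or all(a.size == 0 for a in changes.ab):
        raise ValueError("no paired changes to tabulate")
    rows = []
    for net_id, ab, cb, labels in zip(
        changes.network_ids, changes.ab, changes.cb, changes.labels
    ):
        for (study, k, l), a, c in zip(labels, ab, cb):
            rows.append(
                {
                    "network": net_id,
                    "study": study,
                    "pair": f"{k} vs {l}",
                    "ab": float(a),
                    "cb": float(c),
                    "deviation": float(abs(a - c)),
                    "flagged": bool(abs(a - c) > deviation_threshold),
                }
            )
    return pd.DataFrame(rows)


def deviation_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-network flagged / total cell counts from a scatter table."""
    g = table.groupby("network")["flagged"]
    out = g.agg(flagged="sum", total="count").reset_index()
    out["proportion"] = out["flagged"] / out["total"]
    return out


def agreement_summary(changes: PairedChanges, test: EtaTest) -> dict:
    ab, cb = changes.pooled()
    ba = bland_altman(ab, cb)
    return {
        "mean_difference": ba.mean_difference,
        "sd_difference": ba.sd_difference,
        "limits_of_agreement": list(ba.limits_of_agreement),
        "pct_within_limits": ba.pct_within_limits,
        "n_pairs": ba.n,
        "eta_ab": test.eta_ab,
        "eta_cb": test.eta_cb,
        "ci_ab": list(test.ci_ab),
        "ci_cb": list(test.ci_cb),
        "p_value": test.p_value,
        "n_networks": test.n_networks,
        "n_boot": test.n_boot,
    }
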