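"""Leave-one-trial-out sensitivity engine.

The procedure, per network:

1. Fit the arm-based and contrast-based models to the complete data.
2. Remove each trial in turn and refit both models.
3. Express the impact on each population-averaged risk as a *fold change*,
   oriented to be >= 1: max(pi_reduced/pi_full, pi_full/pi_reduced).
4. Express the impact on each pairwise odds ratio as a log-OR change
   log(OR_reduced / OR_full), from both approaches.
5. (Cross-network, see :mod:`nmaloo.agreement`) compare the two approaches.
6. Record whether the best treatment (by Pbest) changes.
7. Re-assess inconsistency for a designated pair where it stays eligible.

An exclusion is *ineligible* (skipped for the affected metrics, never fatal)
when it removes a treatment entirely or disconnects the network; sampler
failures are caught and recorded per exclusion.  Seeds are derived
deterministically from (base seed, network, stage, study), so results are
reproducible end to end and adding a network does not shift other streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .ab_model import ABDerived, ABPosterior, ABPriors, derive_ab, fit_ab
from .cb_model import CBPosterior, CBPriors, fit_cb, or_matrix_from_d
from .inconsistency import DiscrepancyResult, fit_discrepancy, partition_trials
from .mcmc import MCMCConfig, derive_seed
from .network_data import NMANetwork, remove_trial, validate_inclusion

logger = logging.getLogger("nmaloo")

#: half-open fold-change bins; the first interval is closed at both ends
FOLD_BINS = (1.00, 1.10, 1.20, 1.30, 1.40, 1.50)
FOLD_BIN_LABELS = (
    "[1.00,1.10]",
    "(1.10,1.20]",
    "(1.20,1.30]",
    "(1.30,1.40]",
    "(1.40,1.50]",
    ">1.50",
)


def fold_change(pi_full: float, pi_reduced: float) -> float:
    """Oriented ratio of event rates, always >= 1.

    A full-network rate of 0.70 dropping to 0.50 is a 1.40-fold change;
    0.40 rising to 0.60 is a 1.50-fold change.
    """
    pi_full = float(pi_full)
    pi_reduced = float(pi_reduced)
    if not (0.0 < pi_full < 1.0 and 0.0 < pi_reduced < 1.0):
        raise ValueError("event rates must lie strictly inside (0, 1)")
    r = pi_reduced / pi_full
    return max(r, 1.0 / r)


def logor_change(or_reduced: float, or_full: float) -> float:
    """log(OR_reduced / OR_full); zero means the exclusion had no impact."""
    if or_reduced <= 0 or or_full <= 0:
        raise ValueError("odds ratios must be positive")
    return float(np.log(or_reduced / or_full))


def bin_fold_changes(values: Sequence[float]) -> np.ndarray:
    """Proportions in [1.00,1.10], (1.10,1.20], ..., (1.40,1.50], (1.50, inf).

    The first interval is closed at 1.10; every later interval is half-open
    (a, b].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no fold changes to bin")
    if np.any(v < 1.0):
        raise ValueError("fold changes must be >= 1")
    counts = np.zeros(6)
    counts[0] = np.sum(v <= FOLD_BINS[1])
    for j in range(1, 5):
        counts[j] = np.sum((v > FOLD_BINS[j]) & (v <= FOLD_BINS[j + 1]))
    counts[5] = np.sum(v > FOLD_BINS[5])
    return counts / v.size


@dataclass(frozen=True)
class BestTreatmentChange:
    study_id: str
    full_best: str
    new_best: str
    new_pbest: float
    tie: bool = False


def best_treatment_change(
    full_derived: ABDerived,
    reduced_derived: ABDerived,
    study_id: str = "",
) -> BestTreatmentChange | None:
    """Report the new best treatment (and its Pbest) when it differs from the
    full network's; ``None`` when the ranking is unchanged.  Ties go to the
    lowest-indexed treatment and are flagged."""
    if full_derived.treatments != reduced_derived.treatments:
        raise ValueError("treatment sets differ between full and reduced fits")
    full_best, _ = full_derived.best_treatment()
    new_best, new_p = reduced_derived.best_treatment()
    if new_best == full_best:
        return None
    tie = int(np.sum(reduced_derived.pbest == reduced_derived.pbest.max())) > 1
    if tie:
        logger.info("Pbest tie in reduced fit (excluding %s); lowest index reported", study_id)
    return BestTreatmentChange(study_id, full_best, new_best, float(new_p), tie)


@dataclass(frozen=True)
class ExclusionRecord:
    """Full-versus-reduced comparison for a single excluded trial."""

    excluded_study: str
    eligible: bool
    reason: str = ""
    ab_pi_reduced: np.ndarray | None = None      # (K,)
    ab_or_reduced: np.ndarray | None = None      # (K, K) plug-in
    cb_or_reduced: np.ndarray | None = None      # (K, K) plug-in
    fold_changes: np.ndarray | None = None       # (K,)
    ab_logor_changes: np.ndarray | None = None   # (K, K), antisymmetric
    cb_logor_changes: np.ndarray | None = None   # (K, K), antisymmetric
    best_change: BestTreatmentChange | None = None
    reduced_pbest: np.ndarray | None = None
    inconsistency_reduced: DiscrepancyResult | None = None
    inconsistency_note: str = ""
    converged: bool = True
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class LOOOptions:
    point_estimate: Literal["mean", "median"] = "mean"   # for AB risks
    cb_point_estimate: Literal["mean", "median"] = "median"  # for CB d
    reference: str | None = None
    inconsistency_pair: tuple[str, str] | None = None
    inconsistency_level: float = 0.95
    ab_priors: ABPriors = field(default_factory=ABPriors)
    cb_priors: CBPriors = field(default_factory=CBPriors)


@dataclass(frozen=True)
class LOOResult:
    network: NMANetwork
    ab_posterior: ABPosterior
    ab_derived: ABDerived
    cb_posterior: CBPosterior
    ab_or_full: np.ndarray
    cb_or_full: np.ndarray
    records: tuple[ExclusionRecord, ...]
    inconsistency_full: DiscrepancyResult | None = None

    def eligible_records(self) -> tuple[ExclusionRecord, ...]:
        return tuple(r for r in self.records if r.eligible)


def _cfg_with_seed(config: MCMCConfig, seed: int) -> MCMCConfig:
    return MCMCConfig(
        n_chains=config.n_chains,
        n_adapt=config.n_adapt,
        n_burnin=config.n_burnin,
        n_iter=config.n_iter,
        thin=config.thin,
        seed=seed,
        rhat_threshold=config.rhat_threshold,
    )


def run_loo(
    net: NMANetwork,
    config: MCMCConfig,
    options: LOOOptions | None = None,
) -> LOOResult:
    """Steps 1-7 for one network: full fits, per-trial exclusions, changes."""
    options = options or LOOOptions()
    report = validate_inclusion(net)
    if not report.passed:
        raise ValueError(
            f"network {net.name!r} fails the inclusion rule "
            f"(low-frequency treatments: {report.low_frequency_treatments}, "
            f"connected: {report.connected})"
        )
    base = config.seed
    ab_post = fit_ab(net, _cfg_with_seed(config, derive_seed(base, net.name, "ab", "full")),
                     options.ab_priors)
    ab_der = derive_ab(ab_post, net.outcome_direction, options.point_estimate)
    cb_post = fit_cb(net, _cfg_with_seed(config, derive_seed(base, net.name, "cb", "full")),
                     options.cb_priors, options.reference)
    ab_or_full = ab_der.or_point
    cb_or_full = or_matrix_from_d(cb_post.d_point(options.cb_point_estimate))

    incon_full = None
    if options.inconsistency_pair is not None:
        k1, k2 = options.inconsistency_pair
        if partition_trials(net, k1, k2).eligible:
            incon_full = fit_discrepancy(
                net, k1, k2,
                _cfg_with_seed(config, derive_seed(base, net.name, "incon", "full")),
                options.inconsistency_level, options.ab_priors,
            )

    records = []
    for sid in net.study_ids:
        records.append(
            _one_exclusion(net, sid, config, options, ab_der, ab_or_full, cb_or_full)
        )
    return LOOResult(
        network=net,
        ab_posterior=ab_post,
        ab_derived=ab_der,
        cb_posterior=cb_post,
        ab_or_full=ab_or_full,
        cb_or_full=cb_or_full,
        records=tuple(records),
        inconsistency_full=incon_full,
    )


def _one_exclusion(
    net: NMANetwork,
    sid: str,
    config: MCMCConfig,
    options: LOOOptions,
    ab_der_full: ABDerived,
    ab_or_full: np.ndarray,
    cb_or_full: np.ndarray,
) -> ExclusionRecord:
    import networkx as nx

    from .network_data import comparison_graph

    reduced = remove_trial(net, sid)
    if reduced.n_treatments < net.n_treatments:
        lost = set(net.treatments) - set(reduced.treatments)
        return ExclusionRecord(sid, False, f"treatment(s) removed: {sorted(lost)}")
    if not nx.is_connected(comparison_graph(reduced)):
        return ExclusionRecord(sid, False, "disconnected")

    base = config.seed
    try:
        ab_post = fit_ab(
            reduced,
            _cfg_with_seed(config, derive_seed(base, net.name, "ab", sid)),
            options.ab_priors,
        )
        ab_der = derive_ab(ab_post, net.outcome_direction, options.point_estimate)
        cb_post = fit_cb(
            reduced,
            _cfg_with_seed(config, derive_seed(base, net.name, "cb", sid)),
            options.cb_priors, options.reference,
        )
    except Exception as exc:  # sampler failures are per-record, never fatal
        logger.warning("exclusion of %s failed: %s", sid, exc)
        return ExclusionRecord(sid, False, f"fit failed: {exc}")

    pi_full = ab_der_full.pi_point
    pi_red = ab_der.pi_point
    folds = np.array([fold_change(pi_full[k], pi_red[k]) for k in range(len(pi_full))])
    ab_or_red = ab_der.or_point
    cb_or_red = or_matrix_from_d(cb_post.d_point(options.cb_point_estimate))
    with np.errstate(divide="ignore"):
        ab_dlor = np.log(ab_or_red / ab_or_full)
        cb_dlor = np.log(cb_or_red / cb_or_full)
    np.fill_diagonal(ab_dlor, 0.0)
    np.fill_diagonal(cb_dlor, 0.0)

    incon = None
    note = ""
    if options.inconsistency_pair is not None:
        k1, k2 = options.inconsistency_pair
        if k1 in reduced.treatments and k2 in reduced.treatments and \
                partition_trials(reduced, k1, k2).eligible:
            try:
                incon = fit_discrepancy(
                    reduced, k1, k2,
                    _cfg_with_seed(config, derive_seed(base, net.name, "incon", sid)),
                    options.inconsistency_level, options.ab_priors,
                )
            except Exception as exc:
                note = f"inconsistency fit failed: {exc}"
        else:
            note = "pair ineligible after exclusion"

    warns = ab_post.warnings + cb_post.warnings
    return ExclusionRecord(
        excluded_study=sid,
        eligible=True,
        ab_pi_reduced=pi_red,
        ab_or_reduced=ab_or_red,
        cb_or_reduced=cb_or_red,
        fold_changes=folds,
        ab_logor_changes=ab_dlor,
        cb_logor_changes=cb_dlor,
        best_change=best_treatment_change(ab_der_full, ab_der, sid),
        reduced_pbest=ab_der.pbest,
        inconsistency_reduced=incon,
        inconsistency_note=note,
        converged=not warns,
        warnings=warns,
    )


@dataclass(frozen=True)
class SensitivitySummary:
    """Network-level summary of the sensitivity analysis (fold-change
    statistics and bins, ranking changes, inconsistency changes)."""

    mean_fold_change: float
    sd_fold_change: float
    max_fold_change: float
    bin_proportions: np.ndarray          # 6 proportions, sum to 1
    n_cells: int                         # all eligible (treatment, exclusion) cells
    n_cells_converged: int               # cells from records with clean R-hat
    best_treatment_changes: tuple[BestTreatmentChange, ...]
    inconsistency_changes: tuple[dict, ...]
    full_best: str
    full_pbest: float


def summarize(result: LOOResult) -> SensitivitySummary:
    """Pool fold changes over all eligible (treatment, exclusion) cells."""
    records = result.eligible_records()
    if not records:
        raise ValueError("no eligible exclusion records to summarize")
    folds = np.concatenate([r.fold_changes for r in records])
    n_conv = sum(len(r.fold_changes) for r in records if r.converged)
    best_changes = tuple(r.best_change for r in records if r.best_change is not None)

    incon_changes = []
    full_flag = (
        result.inconsistency_full.inconsistent
        if result.inconsistency_full is not None
        else None
    )
    for r in records:
        if r.inconsistency_reduced is None:
            continue
        red_flag = r.inconsistency_reduced.inconsistent
        if full_flag is not None and red_flag != full_flag:
            incon_changes.append(
                {
                    "study": r.excluded_study,
                    "pair": list(r.inconsistency_reduced.pair),
                    "full": bool(full_flag),
                    "reduced": bool(red_flag),
                }
            )
    full_best, full_p = result.ab_derived.best_treatment()
    return SensitivitySummary(
        mean_fold_change=float(folds.mean()),
        sd_fold_change=float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
        max_fold_change=float(folds.max()),
        bin_proportions=bin_fold_changes(folds),
        n_cells=int(folds.size),
        n_cells_converged=int(n_conv),
        best_treatment_changes=best_changes,
        inconsistency_changes=tuple(incon_changes),
        full_best=full_best,
        full_pbest=float(full_p),
    )
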