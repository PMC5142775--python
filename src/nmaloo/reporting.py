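"""Run configuration, end-to-end orchestration and report generation.

A YAML run config lists networks (files or synthetic specs), the MCMC
profile, per-network analysis options and bootstrap settings; the analyze
command executes the full leave-one-out procedure per network, then the
cross-network agreement comparison, and writes:

* per-network exclusion records (JSON),
* a fold-change summary table (CSV, one network per row),
* a ranking/inconsistency change table (CSV),
* the agreement summary (JSON) plus scatter and Bland-Altman tables (CSV),
* a run manifest recording seeds, option flags and convergence warnings.

Per-network failures are isolated: one broken network never aborts the rest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    PairedChanges,
    agreement_summary,
    bootstrap_eta_test,
    collect_paired_changes,
    deviation_counts,
    scatter_data,
)
from .loo import LOOOptions, LOOResult, run_loo, summarize, FOLD_BIN_LABELS
from .mcmc import MCMCConfig, derive_seed
from .network_data import NMANetwork, read_network, write_network
from .synthetic import (
    ABTruth,
    CBTruth,
    DesignSpec,
    make_benchmark_suite,
    sample_design,
    simulate_ab,
    simulate_cb,
    write_truth_sidecar,
)

logger = logging.getLogger("nmaloo")


@dataclass(frozen=True)
class NetworkJob:
    name: str
    network: NMANetwork
    options: LOOOptions


@dataclass(frozen=True)
class RunConfig:
    seed: int
    output_dir: Path
    mcmc: MCMCConfig
    jobs: tuple[NetworkJob, ...]
    bootstrap_B: int = 10_000
    deviation_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap B must be >= 100")


def _network_from_entry(entry: dict, base_dir: Path, seed: int) -> NMANetwork:
    if "path" in entry:
        return read_network(
            base_dir / entry["path"],
            outcome_direction=entry.get("outcome_direction"),
            name=entry.get("name"),
        )
    spec = entry["synthetic"]
    design = sample_design(
        DesignSpec(
            n_treatments=int(spec["n_treatments"]),
            n_trials=int(spec["n_trials"]),
            seed=int(spec.get("seed", seed)),
        )
    )
    direction = entry.get("outcome_direction", "beneficial")
    name = entry.get("name", f"synthetic-{spec['model']}")
    if spec["model"] == "ab":
        truth = ABTruth(tuple(spec["mu"]), float(spec["sigma"]), float(spec["rho"]))
        return simulate_ab(design, truth, seed=int(spec.get("seed", seed)),
                           name=name, outcome_direction=direction)
    truth = CBTruth(
        float(spec.get("baseline_mean", 0.0)),
        float(spec.get("baseline_sd", 0.5)),
        tuple(spec["d"]),
        float(spec["sigma"]),
    )
    return simulate_cb(design, truth, seed=int(spec.get("seed", seed)),
                       name=name, outcome_direction=direction)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config into a validated RunConfig."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    seed = int(raw.get("seed", 0))
    mc = raw.get("mcmc", {})
    mcmc = MCMCConfig(
        n_chains=int(mc.get("n_chains", 3)),
        n_adapt=int(mc.get("n_adapt", 5_000)),
        n_burnin=int(mc.get("n_burnin", 20_000)),
        n_iter=int(mc.get("n_iter", 50_000)),
        thin=int(mc.get("thin", 5)),
        seed=seed,
        rhat_threshold=float(mc.get("rhat_threshold", 1.1)),
    )
    jobs = []
    for entry in raw.get("networks", []):
        net = _network_from_entry(entry, path.parent, seed)
        pair = entry.get("inconsistency_pair")
        options = LOOOptions(
            point_estimate=raw.get("point_estimate", "mean"),
            cb_point_estimate=raw.get("cb_point_estimate", "median"),
            reference=entry.get("reference"),
            inconsistency_pair=tuple(pair) if pair else None,
            inconsistency_level=float(raw.get("inconsistency_level", 0.95)),
        )
        jobs.append(NetworkJob(net.name, net, options))
    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "results")),
        mcmc=mcmc,
        jobs=tuple(jobs),
        bootstrap_B=int(raw.get("bootstrap", {}).get("B", 10_000)),
        deviation_threshold=float(raw.get("deviation_threshold", 0.1)),
    )


# -- simulate ---------------------------------------------------------------

def cmd_simulate(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the benchmark suite (CSV + YAML sidecars + truth sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for entry in make_benchmark_suite(seed):
        p = out / f"{entry.network.name}.csv"
        write_network(entry.network, p)
        write_truth_sidecar(entry.truth, out / f"{entry.network.name}.truth.yaml")
        paths.append(p)
    return paths


# -- analyze ----------------------------------------------------------------

def _record_payload(rec) -> dict:
    out: dict[str, Any] = {
        "excluded_study": rec.excluded_study,
        "eligible": rec.eligible,
        "reason": rec.reason,
        "converged": rec.converged,
        "warnings": list(rec.warnings),
    }
    if rec.eligible:
        out["ab_pi_reduced"] = [float(x) for x in rec.ab_pi_reduced]
        out["fold_changes"] = [float(x) for x in rec.fold_changes]
        out["max_fold_change"] = float(np.max(rec.fold_changes))
        if rec.best_change is not None:
            out["best_change"] = {
                "new_best": rec.best_change.new_best,
                "new_pbest": rec.best_change.new_pbest,
                "tie": rec.best_change.tie,
            }
        if rec.inconsistency_reduced is not None:
            out["inconsistency"] = {
                "pair": list(rec.inconsistency_reduced.pair),
                "credible_interval": list(rec.inconsistency_reduced.credible_interval),
                "inconsistent": bool(rec.inconsistency_reduced.inconsistent),
            }
        elif rec.inconsistency_note:
            out["inconsistency_note"] = rec.inconsistency_note
    return out


def _table2_row(name: str, summ) -> dict:
    row = {
        "network": name,
        "mean_fold_change": round(summ.mean_fold_change, 3),
        "sd_fold_change": round(summ.sd_fold_change, 3),
        "max_fold_change": round(summ.max_fold_change, 3),
    }
    for label, p in zip(FOLD_BIN_LABELS, summ.bin_proportions):
        row[label] = round(float(p), 3)
    row["n_cells"] = summ.n_cells
    row["n_cells_converged"] = summ.n_cells_converged
    return row


def _table3_row(name: str, summ, result: LOOResult) -> dict:
    if summ.best_treatment_changes:
        changed = "; ".join(
            f"{c.new_best} ({c.new_pbest:.3f}) after omitting {c.study_id}"
            for c in summ.best_treatment_changes
        )
    else:
        changed = "None"
    if result.inconsistency_full is None:
        incon = "-----"
    elif summ.inconsistency_changes:
        incon = "; ".join(
            f"{'appears' if c['reduced'] else 'disappears'} after omitting {c['study']}"
            for c in summ.inconsistency_changes
        )
    else:
        incon = "None"
    return {
        "network": name,
        "full_best": summ.full_best,
        "full_pbest": round(summ.full_pbest, 3),
        "best_treatment_change": changed,
        "inconsistency_change": incon,
    }


def cmd_analyze(config: RunConfig, plots: bool = False) -> Path:
    """Run the full pipeline and write all artifacts to the output dir."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    results: list[LOOResult] = []
    failures: dict[str, str] = {}
    t2_rows, t3_rows = [], []
    for job in config.jobs:
        try:
            res = run_loo(job.network, config.mcmc, job.options)
            summ = summarize(res)
        except Exception as exc:
            logger.error("network %s failed: %s", job.name, exc)
            failures[job.name] = str(exc)
            continue
        results.append(res)
        t2_rows.append(_table2_row(job.name, summ))
        t3_rows.append(_table3_row(job.name, summ, res))
        payload = {
            "network": job.name,
            "treatments": list(res.network.treatments),
            "records": [_record_payload(r) for r in res.records],
        }
        (out / f"{job.name}.records.json").write_text(json.dumps(payload, indent=1))
    if not results:
        raise RuntimeError(f"all networks failed: {failures}")

    pd.DataFrame(t2_rows).to_csv(out / "fold_change_summary.csv", index=False)
    pd.DataFrame(t3_rows).to_csv(out / "ranking_inconsistency_summary.csv", index=False)

    if len(results) >= 2:
        changes = collect_paired_changes(results)
        test = bootstrap_eta_test(
            changes, B=config.bootstrap_B, seed=derive_seed(config.seed, "bootstrap")
        )
        summary = agreement_summary(changes, test)
        (out / "agreement.json").write_text(json.dumps(summary, indent=1))
        table = scatter_data(changes, config.deviation_threshold)
        table.to_csv(out / "scatter.csv", index=False)
        deviation_counts(table).to_csv(out / "deviation_counts.csv", index=False)
        if plots:
            _write_plots(table, summary, out)

    manifest = {
        "nmaloo_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "mcmc": {
            "n_chains": config.mcmc.n_chains,
            "n_adapt": config.mcmc.n_adapt,
            "n_burnin": config.mcmc.n_burnin,
            "n_iter": config.mcmc.n_iter,
            "thin": config.mcmc.thin,
            "rhat_threshold": config.mcmc.rhat_threshold,
        },
        "bootstrap_B": config.bootstrap_B,
        "deviation_threshold": config.deviation_threshold,
        "networks": [
            {
                "name": job.name,
                "point_estimate": job.options.point_estimate,
                "cb_point_estimate": job.options.cb_point_estimate,
                "reference": job.options.reference,
                "inconsistency_pair": list(job.options.inconsistency_pair)
                if job.options.inconsistency_pair else None,
                "inconsistency_level": job.options.inconsistency_level,
            }
            for job in config.jobs
        ],
        "failures": failures,
        "convergence_warnings": {
            r.network.name: list(r.ab_posterior.warnings + r.cb_posterior.warnings)
            for r in results
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _write_plots(table: pd.DataFrame, summary: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["ab"], table["cb"], s=8, alpha=0.5)
    lim = max(table["ab"].abs().max(), table["cb"].abs().max(), 0.01) * 1.1
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=1)
    ax.set_xlabel("log OR change (AB)")
    ax.set_ylabel("log OR change (CB)")
    fig.savefig(out / "scatter.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    d = table["ab"] - table["cb"]
    m = (table["ab"] + table["cb"]) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(m, d, s=8, alpha=0.5)
    ax.axhline(summary["mean_difference"], color="k", ls="--", lw=1)
    for lim_ in summary["limits_of_agreement"]:
        ax.axhline(lim_, color="grey", ls="--", lw=1)
    ax.set_xlabel("mean of AB and CB log OR change")
    ax.set_ylabel("difference (AB - CB)")
    fig.savefig(out / "bland_altman.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


# -- report -----------------------------------------------------------------

def cmd_report(results_dir: str | Path) -> Path:
    """Render a markdown report from an analyze output directory."""
    results_dir = Path(results_dir)
    if not results_dir.exists():
        raise FileNotFoundError(results_dir)
    lines = ["# Leave-one-trial-out sensitivity report", ""]

    t2 = results_dir / "fold_change_summary.csv"
    lines.append("## Fold changes in population-averaged event rates (AB)")
    if t2.exists():
        lines += ["", pd.read_csv(t2).to_markdown(index=False), ""]
    else:
        lines += ["", "_missing_", ""]

    t3 = results_dir / "ranking_inconsistency_summary.csv"
    lines.append("## Treatment ranking and inconsistency changes (AB)")
    if t3.exists():
        lines += ["", pd.read_csv(t3).to_markdown(index=False), ""]
    else:
        lines += ["", "_missing_", ""]

    lines.append("## Agreement between AB and CB approaches")
    ag = results_dir / "agreement.json"
    if ag.exists():
        s = json.loads(ag.read_text())
        lines += [
            "",
            f"- mean difference of log-OR changes: {s['mean_difference']:.4f}",
            f"- SD of differences: {s['sd_difference']:.4f}",
            f"- 95% limits of agreement: [{s['limits_of_agreement'][0]:.4f}, "
            f"{s['limits_of_agreement'][1]:.4f}]",
            f"- proportion within limits: {s['pct_within_limits']:.3f}",
            f"- eta_AB = {s['eta_ab']:.4f} (95% CI {s['ci_ab'][0]:.4f}, {s['ci_ab'][1]:.4f})",
            f"- eta_CB = {s['eta_cb']:.4f} (95% CI {s['ci_cb'][0]:.4f}, {s['ci_cb'][1]:.4f})",
            f"- bootstrap p-value (H0: eta_AB = eta_CB): {s['p_value']:.3f}",
            "",
        ]
    else:
        lines += ["", "_section absent (fewer than two networks analyzed)_", ""]

    report = results_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
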