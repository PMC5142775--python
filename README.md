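# nmaloo — leave-one-trial-out sensitivity analysis for network meta-analysis

Network meta-analysis (NMA) combines direct and indirect evidence to compare
three or more treatments at once.  Because NMAs often include or exclude
trials selectively, a natural robustness question is: *how much does every
estimate move when a single trial is left out?*  `nmaloo` answers that
question for binary outcomes by refitting two Bayesian hierarchical models —
an **arm-based (AB)** model and a **contrast-based (CB)** model — once per
trial exclusion, and quantifying the impact on absolute risks, odds ratios,
treatment rankings and evidence consistency.  It is aimed at biostatisticians
and systematic reviewers who want the sensitivity of an NMA, not just its
point estimates.

## Models

**Arm-based** (probit link, exchangeable correlated trial random effects):

    y_ik ~ Binomial(n_ik, p_ik)
    Φ⁻¹(p_ik) = μ_k + σ v_ik,   (v_i1, …, v_iK)ᵀ ~ MVN(0, R_K)

with R_K an exchangeable correlation matrix (correlation ρ).  The
population-averaged event rate has the closed form
π_k = Φ(μ_k / √(1 + σ²)); marginal odds ratios are formed from the π_k and
the probability of being the best treatment (Pbest) from their posterior
ranks.

**Contrast-based** (Lu & Ades logit form):

    logit(p_ik) = μ_i + X_ik δ_i,b(i),k
    (δ_i,b(i),k) ~ MVN(d_b(i)k, V),   var σ², cov σ²/2

with trial baselines μ_i, basic parameters d_bk versus a network reference,
and consistency d_kl = d_bk − d_bl built in, so OR_kl = exp(d_kl) holds
exactly per posterior draw.

**The sensitivity procedure.** Fit both models to the complete network; then
remove each trial and refit.  Per exclusion the package records *fold
changes* of each π_k (oriented ratios ≥ 1), *log-OR changes*
log(OR⁽ⁱ⁾/OR) from both approaches, changes in the best treatment and its
Pbest, and — for a designated treatment pair — changes in the inconsistency
flag from the four-group discrepancy-factor posterior Δ.  Across networks,
the AB and CB impact metrics are compared with scatter/Bland-Altman
statistics and a network-level bootstrap test of η_AB = η_CB (the mean
absolute log-OR changes).

Posterior sampling uses a vectorized adaptive Metropolis-within-Gibbs engine
written for these two models (exact Gibbs for the CB basic parameters,
non-centered latent effects for the AB model), with split-R̂ convergence
diagnostics.  A synthetic-network generator reproduces the geometry of
published NMA collections so the whole pipeline is testable end to end
without any external data.

## Worked example

```python
import nmaloo as nl

truth  = nl.ABTruth(mu=(-0.3, 0.0, 0.2, 0.4), sigma=0.1, rho=0.3)
design = nl.sample_design(nl.DesignSpec(n_treatments=4, n_trials=16, seed=10))
net    = nl.simulate_ab(design, truth, per_arm_n=1000, seed=10)

result  = nl.run_loo(net, nl.MCMCConfig.test_profile(seed=21))
summary = nl.summarize(result)
print(f"mean fold change {summary.mean_fold_change:.4f}")
print(f"max  fold change {summary.max_fold_change:.4f}")
print("bin proportions  ", summary.bin_proportions.round(3))
print("best treatment   ", summary.full_best, f"(Pbest {summary.full_pbest:.3f})")
```

Output:

```
mean fold change 1.0083
max  fold change 1.0358
bin proportions   [1. 0. 0. 0. 0. 0.]
best treatment    T4 (Pbest 1.000)
```

Read: this homogeneous, well-powered network is robust — no exclusion moves
any population-averaged risk by more than 1.036-fold, so every
(treatment, exclusion) cell falls in the [1.00, 1.10] bin, and T4 (the
largest probit effect, hence the highest event rate on this beneficial
outcome) stays the best treatment.  Sparse, discordant networks behave very
differently: when a treatment appears in only two trials with crude rates
0.200 and 0.714, excluding either trial produces fold changes above 1.4
(see `tests/test_acceptance.py`).

There is also a CLI for file-based workflows:

```sh
nmaloo simulate --out networks --seed 1
nmaloo analyze --config cfg.yaml --plots
nmaloo report results/
```

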