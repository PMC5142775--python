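# Methods

This note documents the models, algorithms, defaults and design choices
behind `nmaloo`, and what its synthetic-data tests do and do not establish.

## Data model

A network is a long table of trial arms (study, treatment, events `y_ik`,
sample size `n_ik`).  Trials must compare at least two distinct treatments;
duplicate (study, treatment) rows are rejected — collapsing dose arms or
other within-trial duplicates is deliberately left to the user, since no
automatic rule is defensible in general.  Zero-event arms are legal data:
the binomial likelihood handles them without continuity corrections.  A
warning is logged when more than 25% of arms have zero events, because
binomial NMA estimates are known to become bias-prone in rare-event
networks; such networks deserve dedicated rare-event methods, which are out
of scope here.

The inclusion rule used throughout requires every treatment to be compared
in at least two trials and the comparison graph to be connected.  Under that
rule a single exclusion can never make a treatment disappear, but it *can*
disconnect the network; the leave-one-out engine treats both situations as
per-exclusion ineligibility rather than errors, so it stays safe on
arbitrary input.

## Arm-based model

    y_ik ~ Binomial(n_ik, p_ik)
    Φ⁻¹(p_ik) = μ_k + σ v_ik,  (v_ik, k ∈ S_i) ~ MVN(0, R_|S_i|)

R is exchangeable with correlation ρ.  Because an exchangeable MVN's
marginal on any subset is again exchangeable, each trial carries only
|S_i| latent effects; their log density uses the rank-one closed forms for
the inverse and determinant of (1−ρ)I + ρJ, so no per-trial factorization is
needed.  The population-averaged rate is π_k = Φ(μ_k / √(1+σ²)), verified
against adaptive quadrature of E[Φ(μ + σZ)] to 1e−6.  Pbest is computed from
the per-draw ranks of π; ties split a draw's mass equally, so the Pbest
vector sums to one by construction.  Outcome direction decides whether the
highest (beneficial) or lowest (harmful) rate ranks best.

Priors (config-overridable): μ_k ~ N(0, 10²), σ ~ U(0, 5),
ρ ~ U(−1/(K−1), 1).  The lower ρ bound keeps the K-dimensional exchangeable
correlation matrix positive definite.

## Contrast-based model

    logit(p_ik) = μ_i + X_ik δ_i,b(i),k
    (δ_i,b(i),k) ~ MVN(d_b(i)k, V_|S_i|−1)

V is the homogeneous-variance exchangeable covariance with correlation 1/2
(variance σ², covariance σ²/2) — the structure implied by consistent
trial-level contrasts.  The trial baseline b(i) is the lowest-indexed
treatment in S_i and the network reference is the first treatment in network
order (both conventional, both configurable).  Basic parameters obey
d_kl = d_bk − d_bl, so OR_kl = exp(d_kl) satisfies the consistency identity
*exactly per draw* — an assertable invariant, not a statistical check.
Priors: μ_i ~ N(0, 10²) iid, d_bk ~ N(0, 10²), σ ~ U(0, 5).

## Sampler

Both models are sampled with adaptive Metropolis-within-Gibbs, vectorized
across trials (trials are conditionally independent given the shared
parameters):

- AB: per-trial vector random walks on the standardized latent effects
  (non-centered, so mixing survives σ → 0), parallel coordinate-wise
  Metropolis on μ (valid because the binomial likelihood factorizes over
  arms and no two treatment effects share an arm), scalar walks on σ and ρ.
- CB: per-trial vector walks on the contrast vectors, parallel per-trial
  walks on the baselines, an *exact Gibbs* draw for d (its conditional is
  Gaussian; the precision contribution Σᵢ TᵢᵀV⁻¹Tᵢ is precomputed once),
  and a scalar walk on σ.

Proposal scales adapt toward a 0.44 acceptance rate in Robbins-Monro
batches of 50 during warm-up and are frozen afterwards, preserving detailed
balance for the retained draws.  Chains are seeded independently from
(seed, chain) sequences; split-R̂ per parameter (via ArviZ) above the
configured threshold (default 1.1) attaches a convergence warning that
propagates into run manifests and per-exclusion records.

Correctness of the sampler is established two ways: a fully independent
grid/quadrature posterior for the two-treatment degenerate network (a
Bayesian random-effects pairwise meta-analysis; agreement of posterior
means within MC error), and seeded parameter-recovery harnesses (95%
credible-interval coverage of generative truths ≥ 90% over 20
replications for both models).

Production defaults mirror common NMA practice (3 chains, 5,000
adaptation, 20,000 burn-in, 50,000 draws thinned by 5).  The *test profile*
(2 chains, 800 adaptation, 700 burn-in, 2,500 kept draws) is what the test
suite and examples use; all problem sizes in the suite (K = 3–6,
I = 8–30 trials, per-arm n = 150–2,000, 12–20 replications) were chosen as
the smallest scales at which the statistical claims are meaningful.

Numerical details: arm probabilities are clipped to [1e−12, 1−1e−12] inside
the likelihood; σ initialization is clipped into (0, 0.8·σ_max) so extreme
prior truncations (used in degenerate fixed-effect tests) remain valid; the
ρ walk rejects proposals within 1e−6 of the positive-definiteness boundary.

## Inconsistency

For a pair (k1, k2), trials partition into (i) both, (ii) k1 only,
(iii) k2 only, (iv) neither; the pair is eligible when (i)–(iii) are all
non-empty.  The discrepancy model is the AB model with group-specific fixed
effects for k1 and k2, implemented by relabeling those arms by group and
refitting — σ and ρ stay shared, group (iv) trials remain in the model (the
partition defines evidence sources, not data exclusion).  The discrepancy
factor

    Δ = (μ_k1⁽ⁱ⁾ − μ_k2⁽ⁱ⁾) − (μ_k1⁽ⁱⁱ⁾ − μ_k2⁽ⁱⁱⁱ⁾)

is antisymmetric in the pair (verified exactly on matched seeds).  "Zero in
the far tail" is operationalized as the central 95% equal-tailed credible
interval excluding zero (level configurable) — the conventional Bayesian
exclusion rule, since no numeric rule is standard.  Each pair needs its own
model fit; the pipeline default assesses one designated pair per network,
with `eligible_pairs` available to sweep all.  The group-split model does
not require a connected relabeled comparison graph: arm-level fixed effects
are identified directly by their arms, so only the connectivity of the
original network is enforced.

## Leave-one-out engine

Change metrics are plug-in comparisons of single per-fit estimates:
posterior-*mean* π_k for fold changes (matching π's definition as a
posterior expectation) and ORs from posterior-mean π (AB) or
posterior-*median* d (CB); both choices are configurable and recorded in
the run manifest.  Fold changes are oriented ratios
max(π⁽ⁱ⁾/π, π/π⁽ⁱ⁾) ≥ 1; their summary bins are
[1.00, 1.10], (1.10, 1.20], (1.20, 1.30], (1.30, 1.40], (1.40, 1.50],
(1.50, ∞) — note the first bin is closed at 1.10.  Summaries report both
the total cell count and the count restricted to exclusions whose refits
passed the R̂ threshold, since the right denominator is arguable.

Every refit reuses the full-fit MCMC settings with a seed derived by a CRC
hash of (base seed, network, stage, study id) — no warm starts, full
independence, end-to-end reproducibility, and adding a network does not
shift any other network's streams.

## AB/CB agreement

Cells are aligned (network, exclusion, treatment-pair) log-OR changes.
η̂_AB and η̂_CB pool *all* cells with equal weight (not network averages).
Bland-Altman limits are mean ± 1.96·SD (sample SD, n−1).  The bootstrap
resamples whole networks with replacement (default B = 10,000); CIs are
percentile.  For the test of η_AB = η_CB the per-cell differences
|ab| − |cb| are recentered by their grand mean before resampling (the
standard construction of a null resampling distribution), and the two-sided
p-value is the proportion of bootstrap statistics at least as extreme as
the observed mean difference.  Networks are sorted canonically before
resampling so results are invariant to input order.  The scatter view flags
cells with |ab − cb| above a threshold (default 0.1 on the log-OR-change
scale; any choice here is a convention, and it is configurable).

## Synthetic networks

The generator emulates the geometry of published binary-outcome NMA
collections: 4–12 treatments, ~9–110 trials, treatment frequencies from 2
upward, mostly incomplete networks with a guaranteed connected design and
every treatment in at least two trials.  Default per-arm sample sizes are
log-uniform on [20, 400] — small-to-moderate trials are exactly the regime
in which excluding one trial moves estimates appreciably.  Outcomes are
simulated under the same AB or CB generative models the pipeline fits.

What the generator does *not* emulate: publication bias, outcome
misclassification, trial-level covariates, dose structure, or model
misspecification (fitting an AB model to CB-generated data and vice versa
is possible but not part of the default checks).  Passing tests therefore
demonstrate internal statistical correctness — the machinery recovers
truths generated under its own assumptions and its decision rules are
calibrated — not robustness of the models to real-data violations of those
assumptions.

## Known limitations

- Random-walk MCMC needs longer runs than gradient-based samplers for large
  networks; the production profile is sized accordingly.
- No rare-event corrections; heavily zero-laden networks get a warning, not
  a fix.
- Inconsistency detection is assessed under the AB framework only, one pair
  per model fit; no node-splitting or design-by-treatment interaction
  variants.
- Leave-*k*-out and treatment-arm-removal analyses are out of scope.
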