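# Methods

## Model

Each (arm j, subset k) cell is an independent binomial with event
probability p_jk and a Beta(α, β) prior, default the non-informative
Beta(1, 1). The posterior is Beta(α + y_jk, β + n_jk − y_jk) in closed
form. All decision quantities are posterior functionals of the subset
relative risks θ_k = p_1k / p_0k and the global relative risk θ; they
are estimated by exact Monte-Carlo sampling: `n_draws` independent
draws from each cell's Beta posterior, combined per draw index
("matched sampling"), so any per-draw functional is itself a posterior
draw. Because the model is fully conjugate, this sampler targets the
exact posterior with zero autocorrelation; the default
`n_draws = 10,000` gives a standard error below 0.005 on any posterior
probability estimate, and the draw count is configurable where more
precision is wanted.

The *global* relative risk needed by the quantitative interaction
statistic is not uniquely defined by subset-level quantities. Default:
events and totals are pooled across subsets within each arm, the same
conjugate update is applied, and θ = p_1·/p_0· is drawn alongside the
subset draws. An alternative (`global_mode="weighted"`) forms the
per-draw ratio of enrollment-weighted mean event probabilities.

## Decision rules

At each analysis, subset k is enriched iff both conditions hold
(strict inequalities throughout):

* influence: P_1k = P(θ_k < λ | data) > γ. λ (default 0.9) encodes the
  minimal clinically relevant relative risk; it is a fixed design input
  and is never calibrated.
* interaction:
  * Millen (K = 2 only): P_2k = P(θ_t/θ_k > η | θ_t ≥ θ_k, data) > τ,
    with t the complementary subset. The conditioning event restricts to
    draws in which k is the better subset; if no draw satisfies it, P_2k
    is reported as 0 (no interaction evidence) with a warning rather
    than NaN, so the decision engine simply does not fire. If both
    subsets somehow qualify (possible only at η = 1 with near-identical
    draws), the tie is broken toward the larger P_1k and logged.
  * Gail–Simon (any K ≥ 2): per draw i, β_k,i = log θ_k,i is
    standardized by σ_k and split by sign into Q⁻_i and Q⁺_i.
    σ_k is the posterior standard deviation of log θ_k, estimated once
    across the full draw matrix and held fixed, so the statistic's
    distribution over draws is a genuine posterior induced by β_k,i
    alone — the minimal reading that makes
    P_quali = P(min{Q⁻, Q⁺} > C₁ | data) a posterior probability. A
    frequentist delta-method plug-in σ_k from the counts is available
    behind `sigma_mode="plugin"`. The quantitative statistic is the
    per-draw sum Σ_k (θ_k,i − θ_i) compared with C₂ (the posterior-mean
    reading would make the probability degenerate at 0 or 1). By
    default either probability exceeding ε triggers the interaction
    condition (`gs_mode="either"`); quali-only, quanti-only and "both"
    modes are exposed.

Enrichment is permanent: the active set shrinks to the qualifying
subset(s), later analyses skip rule evaluation and only update
estimates (a `re-evaluation` variant was considered and rejected — the
real-data replay tables freeze interaction evaluation after enrichment,
and permanence keeps the terminal classification well defined). With a
single active subset no interaction is evaluable, so only estimates are
reported. Patients from dropped subsets are retained for estimation but
excluded from further accrual.

## Simulator

A scenario fixes K, prevalences π_k, experimental-arm allocation
fractions q_k and the cell probabilities p_jk. Patients accrue
uniformly: subset ~ Categorical(π restricted to the active subsets and
renormalized), arm ~ Bernoulli(q_k), outcome ~ Bernoulli(p_jk).
Renormalization means dropped-subset slots are refilled and the trial
always enrolls exactly n patients — matching the published per-subset
mean sample sizes, which exceed n·π_k in the enriched subset. Analyses
occur every time a fixed number of additional patients has enrolled
(default n/4 = 200 of n = 800: three interims plus a terminal
analysis); the rules are applied at every look including the terminal
one, whose firing changes the trial's terminal classification but not
accrual. Enrollment-count scheduling (rather than calendar time) makes
the operating characteristics independent of the recruitment rate.

Seed policy: replication r of a run with master seed s derives all its
randomness from the key (s, r) — the accrual stream from
SeedSequence([s, r, 1]), the posterior draws of analysis ℓ from
SeedSequence([s, r, 2, ℓ]) and the terminal estimation draws from
SeedSequence([s, r, 3]). Analyses are therefore independent but
reproducible, and serial and parallel (joblib) execution are bitwise
identical.

The built-in catalog encodes the K = 2 scenarios 1–4 (null through
strong quantitative interaction in subset A), the K = 3 scenarios 1–7
(quantitative and qualitative interaction mixtures), five K = 3
prevalence patterns, and the K = 2 sensitivity sweeps (π_A ∈ {0.2, 0.4,
0.5, 0.6, 0.8}; q_A ∈ {0.1, 0.3, 0.5, 0.6, 0.9} with q_B solved from
π_A·q_A + (1 − π_A)·q_B = 0.5 so the trial stays 1:1 overall).

What the generator does *not* emulate: non-uniform or time-varying
accrual, dropout or missing outcomes, delayed outcome ascertainment,
overlapping or nested subsets, and misclassified biomarkers. Passing
operating-characteristic checks therefore speak to the design's
behavior under idealized accrual, not to robustness against those
real-data features.

## Threshold calibration

The cutoffs are chosen by grid search: for every grid point the
design-level false positive rate (proportion of null-scenario
replications enriching any subset) and the enrichment power (proportion
of effect-scenario replications ending enriched within the truly
sensitive subset set — enriching a wrong subset counts against power)
are estimated by simulation; among points with FPR ≤ α (default 0.05)
the one maximizing mean power over the effect scenarios is returned,
with ties broken toward lower FPR and then toward the more conservative
cutoffs. Default grids: γ, τ ∈ {0.80, 0.85, 0.90, 0.95} (centered on
the 0.90 operating anchor), η ∈ {1.0, 1.1, 1.25, 1.5},
C₁ ∈ {0.5, 1, 2, 3}, C₂ ∈ {0.05, 0.1, 0.2, 0.3}, and
ε ∈ {0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90, 0.95}. The ε grid spans
(0, 1) rather than clustering near 0.9 because the null posterior
probabilities P_quali and P_quanti concentrate near zero (both
statistics require strong opposite-sign or spread evidence *within* a
draw), so the Gail–Simon rule operates at much smaller ε than the
influence cutoff; with ε restricted to [0.8, 0.95] the rule's power
collapses to ~10% while its false positive rate is ~0, i.e. the grid
would miss the rule's entire operating range.

Common random numbers make the grid comparison low-variance: each
replication's no-enrichment accrual stream and per-look posterior draws
are simulated once, the per-look influence/interaction probabilities are
cached, and every grid point is scanned against the cache. Because
enrichment freezes rule evaluation and accrual is unmodified before the
first firing look, the terminal classification computed this way equals
what per-grid-point trial simulation would produce — verified
replication-by-replication in the test suite. Near the feasibility
boundary the argmax is still Monte-Carlo noisy: grid points whose true
FPR sits at ≈ α enter or leave the feasible set from seed to seed, so
the selected thresholds (and hence downstream operating
characteristics) can vary between calibration runs at n_cal = 1000.

## Numerical and degenerate-input choices

* Credibility intervals are equal-tailed 2.5/97.5% posterior quantiles.
* Strict inequalities everywhere; ties have probability zero under
  continuous draws. A draw with β_k = 0 exactly contributes to neither
  Q⁻ nor Q⁺.
* Empty cells are handled by the prior (Beta draws are a.s. in (0, 1),
  so relative-risk draws are a.s. finite and positive); a subset with
  zero enrollment keeps its flat prior and cannot pass the influence
  condition at γ ≥ 0.5.
* Degenerate draw matrices with zero variance in some subset make σ_k
  undefined and raise an error.
* Scenario validation requires p_0k > 0 so every true θ_k is finite.

## Real-trial replay

`analyze_trial` applies the same rules to a completed trial's
patient-level records at a fixed calendar of cumulative enrollment
counts. After an enrichment fires, only patients from the enriched
subset(s) are counted as enrolled (others are skipped in the stream),
rule evaluation stops, and dropped subsets' posterior estimates stay
frozen at their enrichment-look values; the global and active-subset
estimates keep updating. Replaying a simulated trial's own patient
stream with the same seeds reproduces the simulator's decision path
exactly (tested), so the two execution paths cannot drift apart.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the simulation study at
n_cal = 1000 calibration replications, N = 1000 operating-characteristic
replications of n = 800 patients, and 10,000 posterior draws per
analysis — sizes at which a full run completes in minutes on one CPU
while keeping the Monte-Carlo standard error of any reported proportion
below about 1.6 percentage points. Unit and property tests use smaller
sizes chosen per test to keep assertions sharp.

## Known limitations

* The Millen criterion is defined only for K = 2; for K ≥ 3 the
  Gail–Simon rule is the only option.
* The calibrated thresholds are estimates: the argmax of a noisy
  surface. Reported operating characteristics should be validated at
  the chosen thresholds with a fresh seed (the suite does this for the
  false-positive constraint).
* No early stopping for overall futility or efficacy: the trial always
  runs to n enrolled.
* Binary outcomes on the relative-risk scale only; odds-ratio or
  survival extensions are out of scope.
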