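"""Patient-level trial simulator with enrichment-aware accrual.

A scenario fixes the data-generating truth (subset prevalences pi_k,
per-subset experimental-arm allocation q_k, per-arm event probabilities
p_jk). Patients accrue uniformly; analyses occur every time a fixed
number of additional patients has been enrolled (default n/4 = 200 of
n = 800, i.e. three interims plus a terminal analysis). When the
decision rules fire, accrual is restricted to the enriched subset(s)
(prevalence renormalized, so the trial still enrolls exactly n
patients) and rule evaluation is frozen; estimation always uses all
enrolled patients, including those from dropped subsets.

Seed policy: one master key per replication; the accrual stream and
each analysis' posterior draws get deterministic sub-seeds derived from
(key, stage), so interim analyses are independent but reproducible and
serial/parallel execution give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .decision import (
    Decision,
    EnrichmentState,
    Thresholds,
    evaluate_analysis,
    posterior_summaries,
    update_enrichment_state,
)
from .posterior import BETA_UNIFORM_PRIOR, BetaParams, SubsetArmCounts, sample_posterior

__all__ = [
    "Scenario",
    "PatientRecord",
    "LookRecord",
    "TrialResult",
    "OperatingCharacteristics",
    "generate_patient",
    "generate_cohort",
    "run_trial",
    "replicate",
    "seed_key",
    "accrual_rng",
    "analysis_seed",
    "ENTIRE_POPULATION",
    "enrich_label",
    "canonical_outcomes",
]

ENTIRE_POPULATION = "entire_population"


def enrich_label(subsets: Sequence[str]) -> str:
    """Canonical terminal-classification key for an enriched subset set."""
    return "enrich:" + "+".join(sorted(subsets))


def canonical_outcomes(subsets: Sequence[str]) -> list[str]:
    """Exhaustive terminal classification set: entire population plus
    every nonempty subset combination (singletons, pairs, ...)."""
    out = [ENTIRE_POPULATION]
    for r in range(1, len(subsets) + 1):
        for combo in combinations(sorted(subsets), r):
            if r == len(subsets) and r > 1:
                continue  # enriching every subset is recorded if observed, not canonical
            out.append(enrich_label(combo))
    return out


def seed_key(master_seed) -> tuple[int, ...]:
    """Normalize a master seed (int or tuple of ints) to a tuple key."""
    if isinstance(master_seed, (int, np.integer)):
        key = (int(master_seed),)
    else:
        key = tuple(int(x) for x in master_seed)
    if any(x < 0 for x in key):
        raise ValueError("seed components must be nonnegative")
    return key


def accrual_rng(key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key) + [1]))


def analysis_seed(key: tuple[int, ...], look: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(list(key) + [2, int(look)])


def _terminal_seed(key: tuple[int, ...]) -> np.random.SeedSequence:
    return np.random.SeedSequence(list(key) + [3])


@dataclass(frozen=True)
class Scenario:
    """Data-generating truth for one simulated trial world."""

    subsets: tuple[str, ...]
    pi: np.ndarray
    q: np.ndarray
    p1: np.ndarray
    p0: np.ndarray
    label: str = ""
    null: bool = False
    sensitive: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "subsets", tuple(str(s) for s in self.subsets))
        for name in ("pi", "q", "p1", "p0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "sensitive", tuple(self.sensitive))
        K = len(self.subsets)
        if K < 2:
            raise ValueError("a scenario needs K >= 2 subsets")
        for name in ("pi", "q", "p1", "p0"):
            arr = getattr(self, name)
            if arr.shape != (K,):
                raise ValueError(f"{name} must have one entry per subset")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        if (self.p0 <= 0).any():
            raise ValueError("control-arm event probabilities must be positive (theta_k finite)")
        if not set(self.sensitive) <= set(self.subsets):
            raise ValueError("sensitive subsets must be scenario subsets")

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    @property
    def theta(self) -> np.ndarray:
        """True subset relative risks p_1k / p_0k."""
        return self.p1 / self.p0


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled patient: enrollment order, biomarker subset,
    randomized arm (1 = experimental), and binary outcome (1 = event)."""

    index: int
    subset: str
    arm: int
    outcome: int


def generate_cohort(
    scenario: Scenario,
    active_subsets: Sequence[str],
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized accrual of ``size`` patients from the active subsets.

    Subset membership is drawn from the scenario prevalences restricted
    to the active subsets and renormalized; arm assignment is
    Bernoulli(q_k) and the outcome Bernoulli(p_{arm,k}). Returns
    (subset_idx, arm, outcome) arrays with subset indices into
    ``scenario.subsets``.
    """
    active = [scenario.subsets.index(lab) for lab in active_subsets]
    if not active:
        raise ValueError("active_subsets must be nonempty")
    pr = scenario.pi[active]
    if pr.sum() <= 0:
        raise ValueError("active subsets have zero total prevalence")
    pr = pr / pr.sum()
    ks = rng.choice(np.asarray(active), size=size, p=pr)
    arm = (rng.random(size) < scenario.q[ks]).astype(np.int64)
    p_event = np.where(arm == 1, scenario.p1[ks], scenario.p0[ks])
    outcome = (rng.random(size) < p_event).astype(np.int64)
    return ks, arm, outcome


def generate_patient(
    scenario: Scenario,
    active_subsets: Sequence[str],
    rng: np.random.Generator,
    index: int = 0,
) -> PatientRecord:
    """Draw a single patient (convenience wrapper over the cohort sampler)."""
    ks, arm, outcome = generate_cohort(scenario, active_subsets, 1, rng)
    return PatientRecord(
        index=index, subset=scenario.subsets[int(ks[0])], arm=int(arm[0]), outcome=int(outcome[0])
    )


@dataclass(frozen=True)
class LookRecord:
    """State at one analysis: cumulative per-subset enrollment, whether
    the rules were evaluated, and the resulting decision (None once the
    enrichment state is frozen)."""

    look: int
    n_cum: np.ndarray
    evaluated: bool
    decision: Optional[Decision]
    active_after: tuple[str, ...]


@dataclass(frozen=True)
class TrialResult:
    """One replication's full decision path and terminal estimates."""

    scenario_label: str
    subsets: tuple[str, ...]
    looks: tuple[LookRecord, ...]
    final_action: str
    enriched: tuple[str, ...]
    enrichment_look: Optional[int]
    n_enrolled: np.ndarray
    theta_hat: dict
    theta_bias: np.ndarray
    seed: tuple[int, ...]
    patients: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default=None, repr=False
    )


def run_trial(
    scenario: Scenario,
    thresholds: Thresholds,
    n_total: int = 800,
    n_analyses: int = 4,
    prior: BetaParams = BETA_UNIFORM_PRIOR,
    n_draws: int = 10_000,
    master_seed=0,
    keep_patients: bool = False,
) -> TrialResult:
    """Simulate one trial: accrue, analyze at each look, enrich, estimate.

    The rules are applied at every look (interims and terminal) until an
    enrichment fires, after which accrual is restricted and evaluation
    frozen. The terminal analysis always computes posterior estimates of
    every theta_k (and the global theta) from all enrolled patients.
    """
    if n_total <= 0 or n_analyses <= 0 or n_total % n_analyses != 0:
        raise ValueError("n_total must be a positive multiple of n_analyses")
    key = seed_key(master_seed)
    rng = accrual_rng(key)
    seg = n_total // n_analyses
    K = scenario.n_subsets

    state = EnrichmentState(active=scenario.subsets, frozen=False)
    events = np.zeros((2, K), dtype=np.int64)
    totals = np.zeros((2, K), dtype=np.int64)
    n_cum = np.zeros(K, dtype=np.int64)
    looks: list[LookRecord] = []
    enrichment_look: Optional[int] = None
    all_patients: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    for look in range(n_analyses):
        ks, arm, outcome = generate_cohort(scenario, state.active, seg, rng)
        if keep_patients:
            all_patients.append((ks, arm, outcome))
        np.add.at(totals, (arm, ks), 1)
        np.add.at(events, (arm, ks), outcome)
        n_cum += np.bincount(ks, minlength=K)

        decision = None
        evaluated = False
        if not state.frozen and len(state.active) >= 2:
            counts = SubsetArmCounts(scenario.subsets, events.copy(), totals.copy())
            decision = evaluate_analysis(
                counts,
                state.active,
                thresholds,
                prior=prior,
                n_draws=n_draws,
                seed=analysis_seed(key, look),
            )
            evaluated = True
            new_state = update_enrichment_state(state, decision)
            if new_state.frozen and not state.frozen:
                enrichment_look = look
            state = new_state
        looks.append(
            LookRecord(
                look=look,
                n_cum=n_cum.copy(),
                evaluated=evaluated,
                decision=decision,
                active_after=state.active,
            )
        )

    final_counts = SubsetArmCounts(scenario.subsets, events, totals)
    final_draws = sample_posterior(
        final_counts, prior=prior, n_draws=n_draws, seed=_terminal_seed(key)
    )
    theta_hat = posterior_summaries(final_draws)
    post_means = np.array([theta_hat[lab]["mean"] for lab in scenario.subsets])
    theta_bias = post_means - scenario.theta

    enriched = tuple(sorted(state.active)) if state.frozen else ()
    final_action = enrich_label(enriched) if enriched else ENTIRE_POPULATION

    patients = None
    if keep_patients:
        patients = tuple(np.concatenate([seg_arr[i] for seg_arr in all_patients]) for i in range(3))

    return TrialResult(
        scenario_label=scenario.label,
        subsets=scenario.subsets,
        looks=tuple(looks),
        final_action=final_action,
        enriched=enriched,
        enrichment_look=enrichment_look,
        n_enrolled=n_cum,
        theta_hat=theta_hat,
        theta_bias=theta_bias,
        seed=key,
        patients=patients,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated behavior of the design over N replications."""

    scenario_label: str
    rule: str
    subsets: tuple[str, ...]
    N: int
    n_total: int
    n_analyses: int
    decision_proportions: dict[str, float]
    mean_n: dict[str, float]
    mean_bias_theta: dict[str, float]
    false_positive_rate: Optional[float]
    correct_enrichment_rate: Optional[float]
    null: bool
    sensitive: tuple[str, ...]

    def proportion(self, outcome: str) -> float:
        return self.decision_proportions.get(outcome, 0.0)

    def enrich_proportion(self, *subsets: str) -> float:
        """Proportion of replications ending enriched in exactly these subsets."""
        return self.proportion(enrich_label(subsets))

    def any_enrichment_rate(self) -> float:
        return 1.0 - self.proportion(ENTIRE_POPULATION)


def aggregate_results(
    results: Sequence[TrialResult],
    scenario: Scenario,
    thresholds: Thresholds,
    n_total: int,
    n_analyses: int,
) -> OperatingCharacteristics:
    """Summarize replications into operating characteristics.

    The false positive rate is the proportion of replications enriching
    any subset under a null scenario; under a non-null scenario it is
    the proportion enriching any subset with no true effect (e.g. the
    enrichment proportion of the no-effect subset).
    """
    N = len(results)
    outcomes = canonical_outcomes(scenario.subsets)
    props = dict.fromkeys(outcomes, 0.0)
    sensitive = set(scenario.sensitive)
    n_fp = 0
    n_correct = 0
    for r in results:
        props[r.final_action] = props.get(r.final_action, 0.0) + 1.0
        if r.enriched:
            if scenario.null or (set(r.enriched) - sensitive):
                n_fp += 1
            if sensitive and set(r.enriched) <= sensitive:
                n_correct += 1
    props = {k: v / N for k, v in props.items()}
    mean_n = dict(
        zip(scenario.subsets, np.mean([r.n_enrolled for r in results], axis=0).tolist())
    )
    mean_bias = dict(
        zip(scenario.subsets, np.mean([r.theta_bias for r in results], axis=0).tolist())
    )
    return OperatingCharacteristics(
        scenario_label=scenario.label,
        rule=thresholds.rule,
        subsets=scenario.subsets,
        N=N,
        n_total=n_total,
        n_analyses=n_analyses,
        decision_proportions=props,
        mean_n=mean_n,
        mean_bias_theta=mean_bias,
        false_positive_rate=n_fp / N,
        correct_enrichment_rate=(n_correct / N) if sensitive else None,
        null=scenario.null,
        sensitive=scenario.sensitive,
    )


def replicate(
    scenario: Scenario,
    thresholds: Thresholds,
    n_total: int = 800,
    n_analyses: int = 4,
    prior: BetaParams = BETA_UNIFORM_PRIOR,
    n_draws: int = 10_000,
    N: int = 1000,
    master_seed=0,
    n_jobs: int = 1,
    keep_results: bool = False,
):
    """Run N independent replications and aggregate their operating
    characteristics.

    Replication r derives its seeds from (master_seed, r), so results
    are bitwise identical whether run serially or in parallel (joblib).
    Returns the OperatingCharacteristics, or ``(oc, results)`` when
    ``keep_results`` is set.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    base = seed_key(master_seed)

    def one(r: int) -> TrialResult:
        return run_trial(
            scenario,
            thresholds,
            n_total=n_total,
            n_analyses=n_analyses,
            prior=prior,
            n_draws=n_draws,
            master_seed=base + (r,),
        )

    if n_jobs == 1:
        results = [one(r) for r in range(N)]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(N))

    oc = aggregate_results(results, scenario, thresholds, n_total, n_analyses)
    if keep_results:
        return oc, results
    return oc
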