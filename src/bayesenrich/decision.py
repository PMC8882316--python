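"""Interim/terminal decision rules and the enrichment state machine.

At each analysis every active subset k is checked against two posterior
conditions:

* influence:   P_1k = P(theta_k < lambda | data) > gamma
* interaction: (Millen)      P_2k > tau, or
               (Gail–Simon)  P_quali > epsilon and/or P_quanti > epsilon

A subset joins the enriched set iff both hold; otherwise the trial
continues in the entire (currently active) population. Once an
enrichment fires, accrual is restricted to the enriched subset(s) and
rule evaluation is frozen for the remainder of the trial (estimates are
still updated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .interaction import interaction_result, InteractionResult
from .posterior import (
    BETA_UNIFORM_PRIOR,
    BetaParams,
    PosteriorDraws,
    SubsetArmCounts,
    influence_probability,
    sample_posterior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "Decision",
    "EnrichmentState",
    "evaluate_analysis",
    "update_enrichment_state",
    "posterior_summaries",
]

RULES = ("millen", "gail_simon")
GS_MODES = ("quali", "quanti", "either", "both")


@dataclass(frozen=True)
class Thresholds:
    """All decision cutoffs of the design in one object.

    ``lam`` is the minimal clinically relevant relative risk (fixed
    design input, default 0.9, never calibrated); ``gamma`` the
    influence cutoff; ``tau``/``eta`` drive the Millen rule and
    ``epsilon``/``c1``/``c2`` the Gail–Simon rule. ``gs_mode`` selects
    how the two Gail–Simon probabilities combine ("either" = or, as the
    design's default reading of "or/and").
    """

    gamma: float
    rule: str = "millen"
    lam: float = 0.9
    eta: Optional[float] = None
    tau: Optional[float] = None
    epsilon: Optional[float] = None
    c1: Optional[float] = None
    c2: Optional[float] = None
    gs_mode: str = "either"

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.gs_mode not in GS_MODES:
            raise ValueError(f"unknown gs_mode {self.gs_mode!r}; expected one of {GS_MODES}")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.rule == "millen":
            if self.tau is None or self.eta is None:
                raise ValueError("millen rule requires tau and eta")
            if not 0 < self.tau <= 1:
                raise ValueError("tau must lie in (0, 1]")
            if self.eta < 1:
                raise ValueError("eta must be >= 1")
        else:
            if self.epsilon is None:
                raise ValueError("gail_simon rule requires epsilon")
            if not 0 < self.epsilon <= 1:
                raise ValueError("epsilon must lie in (0, 1]")
            need_c1 = self.gs_mode in ("quali", "either", "both")
            need_c2 = self.gs_mode in ("quanti", "either", "both")
            if need_c1 and (self.c1 is None or self.c1 < 0):
                raise ValueError("gail_simon rule requires nonnegative c1")
            if need_c2 and self.c2 is None:
                raise ValueError("gail_simon rule requires c2")

    def replace(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Decision:
    """Outcome of one rule evaluation.

    ``action`` is "enrich" iff ``enriched_subsets`` is nonempty;
    ``per_subset_evidence`` records, per active subset, the influence
    probability, the applicable interaction probability, and the two
    condition flags.
    """

    action: str
    enriched_subsets: tuple[str, ...]
    per_subset_evidence: dict[str, dict]
    interaction: Optional[InteractionResult] = None
    estimates: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.action not in ("continue_entire_population", "enrich"):
            raise ValueError(f"unknown action {self.action!r}")
        if (self.action == "enrich") != bool(self.enriched_subsets):
            raise ValueError("action and enriched_subsets disagree")


@dataclass(frozen=True)
class EnrichmentState:
    """Currently active subsets plus the post-enrichment freeze flag."""

    active: tuple[str, ...]
    frozen: bool = False


def posterior_summaries(draws: PosteriorDraws, levels=(0.025, 0.975)) -> dict:
    """Posterior mean and equal-tailed credibility bounds of each theta_k
    and of the global theta."""
    lo, hi = levels
    out = {}
    for k, lab in enumerate(draws.subsets):
        t = draws.theta[:, k]
        out[lab] = {
            "mean": float(t.mean()),
            "lo": float(np.quantile(t, lo)),
            "hi": float(np.quantile(t, hi)),
        }
    tg = draws.theta_global
    out["__global__"] = {
        "mean": float(tg.mean()),
        "lo": float(np.quantile(tg, lo)),
        "hi": float(np.quantile(tg, hi)),
    }
    return out


def _interaction_met(thresholds: Thresholds, res: InteractionResult, subset: str) -> tuple[bool, float]:
    """Whether the interaction condition holds for ``subset``, plus the
    probability driving it (for reporting)."""
    if thresholds.rule == "millen":
        p2 = res.p2[subset]
        return p2 > thresholds.tau, p2
    eps = thresholds.epsilon
    quali = res.p_quali > eps
    quanti = res.p_quanti > eps
    if thresholds.gs_mode == "quali":
        met = quali
    elif thresholds.gs_mode == "quanti":
        met = quanti
    elif thresholds.gs_mode == "either":
        met = quali or quanti
    else:  # both
        met = quali and quanti
    return met, max(res.p_quali, res.p_quanti)


def evaluate_analysis(
    counts: SubsetArmCounts,
    active_subsets: Sequence[str],
    thresholds: Thresholds,
    prior: BetaParams = BETA_UNIFORM_PRIOR,
    n_draws: int = 10_000,
    seed=None,
    draws: Optional[PosteriorDraws] = None,
) -> Decision:
    """Apply the influence + interaction rules to one analysis snapshot.

    ``counts`` may cover more subsets than are active; only active
    subsets enter the rules. With a single active subset there is no
    comparator, so only estimates are reported (no enrichment). A
    precomputed ``draws`` object (matching the active restriction) may
    be supplied to skip resampling.
    """
    active = tuple(lab for lab in counts.subsets if lab in set(active_subsets))
    if not active:
        raise ValueError("no active subset present in counts")
    restricted = counts.restrict(active) if active != counts.subsets else counts
    if draws is None:
        draws = sample_posterior(restricted, prior=prior, n_draws=n_draws, seed=seed)
    elif draws.subsets != active:
        raise ValueError("supplied draws do not match the active subsets")

    estimates = posterior_summaries(draws)
    if len(active) < 2:
        return Decision(
            action="continue_entire_population",
            enriched_subsets=(),
            per_subset_evidence={
                active[0]: {
                    "p1": influence_probability(draws, active[0], thresholds.lam),
                    "interaction_p": None,
                    "influence_met": None,
                    "interaction_met": None,
                }
            },
            interaction=None,
            estimates=estimates,
        )

    res = interaction_result(
        draws,
        eta=thresholds.eta if len(active) == 2 else None,
        c1=thresholds.c1,
        c2=thresholds.c2,
    )
    if thresholds.rule == "millen" and len(active) != 2:
        raise ValueError("millen rule requires exactly 2 active subsets")

    evidence: dict[str, dict] = {}
    qualifying: list[str] = []
    for lab in active:
        p1 = influence_probability(draws, lab, thresholds.lam)
        influence_met = p1 > thresholds.gamma
        interaction_met, ip = _interaction_met(thresholds, res, lab)
        evidence[lab] = {
            "p1": p1,
            "interaction_p": ip,
            "influence_met": influence_met,
            "interaction_met": interaction_met,
        }
        if influence_met and interaction_met:
            qualifying.append(lab)

    if thresholds.rule == "millen" and len(qualifying) == 2:
        # Possible only with eta = 1 and near-identical draws; break the
        # tie toward the subset with stronger influence evidence.
        a, b = qualifying
        winner = a if evidence[a]["p1"] >= evidence[b]["p1"] else b
        logger.info("both subsets qualify under Millen; tie-break toward %s", winner)
        qualifying = [winner]

    if qualifying:
        return Decision(
            action="enrich",
            enriched_subsets=tuple(qualifying),
            per_subset_evidence=evidence,
            interaction=res,
            estimates=estimates,
        )
    return Decision(
        action="continue_entire_population",
        enriched_subsets=(),
        per_subset_evidence=evidence,
        interaction=res,
        estimates=estimates,
    )


def update_enrichment_state(state: EnrichmentState, decision: Decision) -> EnrichmentState:
    """Advance the enrichment state machine after an analysis.

    Enrichment restricts the active set and freezes rule evaluation for
    all subsequent analyses (estimates only); a continue decision leaves
    the state unchanged.
    """
    if decision.action == "enrich":
        extra = set(decision.enriched_subsets) - set(state.active)
        if extra:
            raise ValueError(f"enriched subsets {extra} not currently active")
        return EnrichmentState(active=tuple(decision.enriched_subsets), frozen=True)
    return state
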