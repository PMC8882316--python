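"""Conjugate Beta-binomial posteriors for subset-level relative risks.

Each cell (arm j, subset k) has an independent binomial likelihood with
event probability ``p_jk`` and a conjugate Beta prior, so the posterior
is available in closed form and can be sampled exactly — no MCMC is
needed. Relative-risk draws ``theta_k = p_1k / p_0k`` are formed from
matched Monte-Carlo draws of the two arms, and a pooled (or
prevalence-weighted) global relative risk is drawn alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BetaParams",
    "SubsetArmCounts",
    "PosteriorDraws",
    "update_beta",
    "sample_posterior",
    "influence_probability",
]

#: Non-informative uniform prior used throughout the design.
BETA_UNIFORM_PRIOR = None  # set below once BetaParams exists


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta prior or posterior; both must be > 0."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shape parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


BETA_UNIFORM_PRIOR = BetaParams(1.0, 1.0)


def update_beta(prior: BetaParams, events: int, totals: int) -> BetaParams:
    """Conjugate update: Beta(a, b) + (y events out of n) -> Beta(a+y, b+n-y)."""
    events = int(events)
    totals = int(totals)
    if events < 0 or totals < 0:
        raise ValueError(f"counts must be nonnegative, got events={events}, totals={totals}")
    if events > totals:
        raise ValueError(f"events ({events}) exceed totals ({totals})")
    return BetaParams(prior.alpha + events, prior.beta + totals - events)


@dataclass(frozen=True)
class SubsetArmCounts:
    """Sufficient statistics per (arm, subset) cell at one analysis.

    ``events[j, k]`` and ``totals[j, k]`` hold the event count ``y_jk``
    and sample size ``n_jk`` for arm ``j`` (0 control, 1 experimental)
    and subset ``subsets[k]``.
    """

    subsets: tuple[str, ...]
    events: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        events = np.asarray(self.events, dtype=np.int64)
        totals = np.asarray(self.totals, dtype=np.int64)
        object.__setattr__(self, "subsets", tuple(str(s) for s in self.subsets))
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "totals", totals)
        K = len(self.subsets)
        if K < 1:
            raise ValueError("at least one subset required")
        if len(set(self.subsets)) != K:
            raise ValueError("duplicate subset labels")
        if events.shape != (2, K) or totals.shape != (2, K):
            raise ValueError(f"events/totals must have shape (2, {K})")
        if (events < 0).any() or (totals < 0).any():
            raise ValueError("negative counts")
        if (events > totals).any():
            raise ValueError("events exceed totals in some cell")

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def index(self, subset: str) -> int:
        try:
            return self.subsets.index(subset)
        except ValueError:
            raise KeyError(f"unknown subset label {subset!r}; have {self.subsets}") from None

    @classmethod
    def from_mappings(
        cls,
        subsets: Sequence[str],
        events: Mapping[tuple[int, str], int],
        totals: Mapping[tuple[int, str], int],
    ) -> "SubsetArmCounts":
        subsets = tuple(subsets)
        ev = np.zeros((2, len(subsets)), dtype=np.int64)
        to = np.zeros((2, len(subsets)), dtype=np.int64)
        for j in (0, 1):
            for k, lab in enumerate(subsets):
                ev[j, k] = events.get((j, lab), 0)
                to[j, k] = totals.get((j, lab), 0)
        return cls(subsets, ev, to)

    @classmethod
    def from_arrays(
        cls,
        subsets: Sequence[str],
        subset_idx: np.ndarray,
        arm: np.ndarray,
        outcome: np.ndarray,
    ) -> "SubsetArmCounts":
        """Tally patient-level arrays (subset index, arm, binary outcome)."""
        K = len(subsets)
        ev = np.zeros((2, K), dtype=np.int64)
        to = np.zeros((2, K), dtype=np.int64)
        for j in (0, 1):
            mask = arm == j
            to[j] = np.bincount(subset_idx[mask], minlength=K)
            ev[j] = np.bincount(subset_idx[mask], weights=outcome[mask], minlength=K)
        return cls(tuple(subsets), ev, to)

    def restrict(self, labels: Sequence[str]) -> "SubsetArmCounts":
        """Keep only the named subsets (order taken from this object)."""
        keep = [k for k, lab in enumerate(self.subsets) if lab in set(labels)]
        if not keep:
            raise ValueError("restriction removes every subset")
        return SubsetArmCounts(
            tuple(self.subsets[k] for k in keep), self.events[:, keep], self.totals[:, keep]
        )

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Events and totals pooled across subsets, one entry per arm."""
        return self.events.sum(axis=1), self.totals.sum(axis=1)

    def __add__(self, other: "SubsetArmCounts") -> "SubsetArmCounts":
        if self.subsets != other.subsets:
            raise ValueError("subset labels differ")
        return SubsetArmCounts(self.subsets, self.events + other.events, self.totals + other.totals)


@dataclass(frozen=True)
class PosteriorDraws:
    """Matched Monte-Carlo draws from the joint conjugate posterior.

    ``p`` has shape (n_draws, 2, K); ``theta`` = ``p[:, 1] / p[:, 0]``
    is computed from the *same* underlying draws (matched sampling), so
    any functional of (p, theta, theta_global) evaluated per draw is a
    draw from its posterior.
    """

    subsets: tuple[str, ...]
    p: np.ndarray
    theta: np.ndarray
    log_theta: np.ndarray
    theta_global: np.ndarray
    n_draws: int
    seed: object = field(repr=False, default=None)

    def index(self, subset: str) -> int:
        try:
            return self.subsets.index(subset)
        except ValueError:
            raise KeyError(f"unknown subset label {subset!r}; have {self.subsets}") from None

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def sample_posterior(
    counts: SubsetArmCounts,
    prior: BetaParams = BETA_UNIFORM_PRIOR,
    n_draws: int = 10_000,
    seed=None,
    global_mode: str = "pooled",
) -> PosteriorDraws:
    """Draw from the exact joint posterior of all ``p_jk`` and ``theta_k``.

    Parameters
    ----------
    counts
        Events and totals per (arm, subset).
    prior
        Common Beta prior for every cell (default uniform Beta(1, 1)).
    n_draws
        Number of Monte-Carlo draws.
    seed
        Anything accepted by :func:`numpy.random.default_rng`.
    global_mode
        How the posterior of the overall relative risk ``theta`` is
        formed: ``"pooled"`` applies the same conjugate update to
        events/totals pooled across subsets within each arm;
        ``"weighted"`` takes the per-draw ratio of enrollment-weighted
        mean event probabilities across subsets.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    K = counts.n_subsets
    alpha = prior.alpha + counts.events
    beta = prior.beta + counts.totals - counts.events
    p = rng.beta(alpha, beta, size=(n_draws, 2, K))
    theta = p[:, 1, :] / p[:, 0, :]

    if global_mode == "pooled":
        ev, tot = counts.pooled()
        a_g = prior.alpha + ev
        b_g = prior.beta + tot - ev
        p_g = rng.beta(a_g, b_g, size=(n_draws, 2))
        theta_global = p_g[:, 1] / p_g[:, 0]
    elif global_mode == "weighted":
        w = counts.totals.sum(axis=0).astype(float)
        if w.sum() <= 0:
            w = np.ones(K)
        w = w / w.sum()
        theta_global = (p[:, 1, :] @ w) / (p[:, 0, :] @ w)
    else:
        raise ValueError(f"unknown global_mode {global_mode!r}")

    return PosteriorDraws(
        subsets=counts.subsets,
        p=p,
        theta=theta,
        log_theta=np.log(theta),
        theta_global=theta_global,
        n_draws=n_draws,
        seed=seed,
    )


def influence_probability(draws: PosteriorDraws, subset: str, lam: float) -> float:
    """Posterior probability that the subset relative risk beats ``lam``.

    This is the influence (efficacy) condition ``P_1k = P(theta_k < lambda
    | data)``; ``lam`` is the minimal clinically relevant effect size
    (design default 0.9). Strict inequality; ties have probability zero.
    """
    if not lam > 0:
        raise ValueError("lam must be positive")
    k = draws.index(subset)
    return float(np.mean(draws.theta[:, k] < lam))
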