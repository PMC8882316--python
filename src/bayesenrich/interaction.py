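"""Posterior treatment-by-subset interaction criteria.

Two families of criteria are implemented on top of the matched
relative-risk draws:

* Millen's conditional ratio (K = 2 only): the posterior probability
  that the worse subset's relative risk exceeds the better one's by at
  least a factor ``eta``, conditional on it being worse at all.
* Bayesianized Gail–Simon statistics (any K >= 2): per posterior draw,
  standardized log relative risks are split by sign into Q- and Q+
  sums; a qualitative interaction is evidenced when both sums are large
  (min{Q-, Q+} > C1), a quantitative one when the subset effects spread
  around the global effect (sum_k (theta_k - theta) > C2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .posterior import PosteriorDraws, SubsetArmCounts

__all__ = [
    "GailSimonDraws",
    "InteractionResult",
    "millen_probability",
    "gail_simon_draws",
    "quali_probability",
    "quanti_probability",
    "interaction_result",
]


class EmptyConditioningWarning(UserWarning):
    """No posterior draw satisfies the Millen conditioning event."""


@dataclass(frozen=True)
class GailSimonDraws:
    """Per-draw Gail–Simon statistics.

    ``beta`` holds the log relative-risk draws (n_draws, K); ``sigma``
    the per-subset posterior standard deviation of log theta_k (held
    fixed across draws); ``q_minus``/``q_plus`` the per-draw sums of
    squared standardized negative/positive terms.
    """

    subsets: tuple[str, ...]
    beta: np.ndarray
    sigma: np.ndarray
    q_minus: np.ndarray
    q_plus: np.ndarray


@dataclass(frozen=True)
class InteractionResult:
    """All interaction probabilities evaluated at one analysis.

    ``p2`` maps subset -> Millen probability P_2k (present only for
    K = 2); ``conditioning_fraction`` maps subset -> fraction of draws
    in the conditioning event used for that subset's P_2k.
    """

    p2: Optional[dict[str, float]]
    p_quali: float
    p_quanti: float
    conditioning_fraction: Optional[dict[str, float]] = None


def millen_probability(
    draws: PosteriorDraws, subset_k: str, subset_t: str, eta: float
) -> tuple[float, float]:
    """Millen's interaction criterion for K = 2 subsets.

    Returns ``(P_2k, conditioning_fraction)`` where
    ``P_2k = P(theta_t / theta_k > eta | theta_t >= theta_k, data)``.
    A large value means the complementary subset ``t`` responds markedly
    worse, i.e. ``k`` is the sensitive subset worth enriching.

    If no draw satisfies the conditioning event the probability is
    reported as 0.0 (no interaction evidence) with a warning.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    if subset_k == subset_t:
        raise ValueError("subset_k and subset_t must differ")
    if draws.n_subsets != 2:
        raise ValueError("Millen's criterion is defined for exactly K=2 subsets")
    tk = draws.theta[:, draws.index(subset_k)]
    tt = draws.theta[:, draws.index(subset_t)]
    cond = tt >= tk
    n_cond = int(cond.sum())
    frac = n_cond / draws.n_draws
    if n_cond == 0:
        warnings.warn(
            f"no draw satisfies theta_{subset_t} >= theta_{subset_k}; "
            "reporting P_2k = 0 (no interaction evidence)",
            EmptyConditioningWarning,
            stacklevel=2,
        )
        return 0.0, 0.0
    p = float(np.mean(tt[cond] / tk[cond] > eta))
    return p, frac


def gail_simon_draws(
    draws: PosteriorDraws,
    sigma_mode: str = "posterior",
    counts: Optional[SubsetArmCounts] = None,
) -> GailSimonDraws:
    """Per-draw Q- and Q+ statistics from the log relative-risk draws.

    ``sigma_mode="posterior"`` (default) standardizes each subset's log
    relative risk by its posterior standard deviation, estimated once
    across all draws and held fixed, so the statistic's distribution
    over draws is a genuine posterior. ``sigma_mode="plugin"`` uses the
    frequentist delta-method standard error of the log relative risk
    computed from ``counts`` instead.
    """
    if draws.n_subsets < 2:
        raise ValueError("Gail-Simon statistics need K >= 2 subsets")
    if draws.n_draws < 2 and sigma_mode == "posterior":
        raise ValueError("at least 2 draws needed to estimate sigma_k")
    beta = draws.log_theta
    if sigma_mode == "posterior":
        sigma = beta.std(axis=0, ddof=1)
    elif sigma_mode == "plugin":
        if counts is None:
            raise ValueError("sigma_mode='plugin' requires counts")
        if counts.subsets != draws.subsets:
            raise ValueError("counts subsets do not match draws")
        y = counts.events.astype(float)
        n = counts.totals.astype(float)
        with np.errstate(divide="ignore"):
            var = (1.0 / y - 1.0 / n).sum(axis=0)
        if not np.all(np.isfinite(var)) or (var <= 0).any():
            raise ValueError("plugin variance undefined (zero events in some cell)")
        sigma = np.sqrt(var)
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if (sigma <= 0).any() or not np.all(np.isfinite(sigma)):
        raise ValueError("degenerate draws: sigma_k undefined in some subset")
    z2 = (beta / sigma) ** 2
    q_minus = np.where(beta < 0, z2, 0.0).sum(axis=1)
    q_plus = np.where(beta > 0, z2, 0.0).sum(axis=1)
    return GailSimonDraws(draws.subsets, beta, sigma, q_minus, q_plus)


def quali_probability(gs: GailSimonDraws, c1: float) -> float:
    """P_quali = P(min{Q-, Q+} > C1 | data): qualitative interaction.

    Positive only when, within a draw, some subsets benefit and others
    are harmed (effects in opposite directions).
    """
    if c1 < 0:
        raise ValueError("c1 must be nonnegative")
    return float(np.mean(np.minimum(gs.q_minus, gs.q_plus) > c1))


def quanti_probability(draws: PosteriorDraws, c2: float) -> float:
    """P_quanti = P(sum_k (theta_k - theta) > C2 | data).

    Per draw, the subset relative risks are compared with the global
    relative risk from the same draw index (matched sampling); the sum
    of deviations measures a quantitative interaction.
    """
    K = draws.n_subsets
    sums = draws.theta.sum(axis=1) - K * draws.theta_global
    return float(np.mean(sums > c2))


def interaction_result(
    draws: PosteriorDraws,
    eta: Optional[float] = None,
    c1: Optional[float] = None,
    c2: Optional[float] = None,
) -> InteractionResult:
    """Evaluate every applicable interaction probability at once.

    Millen's P_2k is computed for each subset (against the complementary
    subset) only when K = 2 and ``eta`` is given; the Gail–Simon
    probabilities require ``c1`` and ``c2``.
    """
    p2 = None
    cond = None
    if draws.n_subsets == 2 and eta is not None:
        a, b = draws.subsets
        p2 = {}
        cond = {}
        p2[a], cond[a] = millen_probability(draws, a, b, eta)
        p2[b], cond[b] = millen_probability(draws, b, a, eta)
    gs = gail_simon_draws(draws)
    p_quali = quali_probability(gs, c1) if c1 is not None else float("nan")
    p_quanti = quanti_probability(draws, c2) if c2 is not None else float("nan")
    return InteractionResult(p2=p2, p_quali=p_quali, p_quanti=p_quanti, conditioning_fraction=cond)
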