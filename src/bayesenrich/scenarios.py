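"""Built-in simulation scenario catalog.

The scenarios encode the data-generating truths of the design's
simulation study: per-arm death probabilities by biomarker subset for
K = 2 (scenarios 1-4, increasing benefit in subset A, none in B) and
K = 3 (scenarios 1-7, mixtures of quantitative and qualitative
interactions), together with the prevalence patterns and the allocation
imbalance sweep used in the sensitivity analyses. Total sample size is
n = 800 with four equally spaced analyses unless overridden.
"""

from __future__ import annotations

import numpy as np

from .simulate import Scenario

__all__ = ["k2_scenario", "k3_scenario", "k3_pattern", "K2_PREVALENCES", "QA_SWEEP", "balanced_q_b"]

# K=2: (p_1A, p_0A, p_1B, p_0B), sensitive subsets, null flag
_K2 = {
    1: ((0.30, 0.30, 0.40, 0.40), (), True),
    2: ((0.30, 0.40, 0.40, 0.40), ("A",), False),
    3: ((0.20, 0.37, 0.40, 0.40), ("A",), False),
    4: ((0.20, 0.50, 0.40, 0.40), ("A",), False),
}

# K=3: (p_1A, p_0A, p_1B, p_0B, p_1C, p_0C), sensitive subsets, null flag
_K3 = {
    1: ((0.40, 0.40, 0.40, 0.40, 0.40, 0.40), (), True),
    2: ((0.32, 0.40, 0.32, 0.40, 0.32, 0.40), ("A", "B", "C"), False),
    3: ((0.40, 0.40, 0.40, 0.40, 0.20, 0.50), ("C",), False),
    4: ((0.40, 0.40, 0.24, 0.40, 0.24, 0.40), ("B", "C"), False),
    5: ((0.40, 0.40, 0.24, 0.40, 0.20, 0.50), ("B", "C"), False),
    6: ((0.40, 0.40, 0.24, 0.40, 0.50, 0.40), ("B",), False),
    7: ((0.40, 0.40, 0.20, 0.50, 0.50, 0.40), ("B",), False),
}

#: Prevalence values of subset A swept in the K=2 sensitivity analysis.
K2_PREVALENCES = (0.2, 0.4, 0.5, 0.6, 0.8)

#: Experimental-arm allocation fractions in subset A swept for K=2.
QA_SWEEP = (0.1, 0.3, 0.5, 0.6, 0.9)

#: K=3 prevalence patterns (pattern 1 is equal prevalence).
_K3_PATTERNS = {
    1: (1 / 3, 1 / 3, 1 / 3),
    2: (1 / 6, 1 / 3, 2 / 4),
    3: (11 / 18, 1 / 3, 1 / 18),
    4: (1 / 3, 2 / 4, 1 / 6),
    5: (1 / 3, 1 / 18, 11 / 18),
}


def k3_pattern(i: int) -> tuple[float, float, float]:
    """Prevalence pattern i (1-5) for the K=3 sensitivity analysis."""
    try:
        return _K3_PATTERNS[i]
    except KeyError:
        raise ValueError(f"unknown K=3 pattern {i}; patterns are 1-5") from None


def balanced_q_b(pi_a: float, q_a: float) -> float:
    """Allocation fraction in subset B restoring overall 1:1 balance.

    Solves pi_A*q_A + (1-pi_A)*q_B = 0.5 for q_B; raises if the solution
    falls outside (0, 1).
    """
    q_b = (0.5 - pi_a * q_a) / (1.0 - pi_a)
    if not 0 < q_b < 1:
        raise ValueError(
            f"no feasible q_B for pi_A={pi_a}, q_A={q_a}: balanced q_B = {q_b:.3f}"
        )
    return q_b


def k2_scenario(i: int, pi_a: float = 0.5, q_a: float = 0.5, q_b: float = None) -> Scenario:
    """Built-in K=2 scenario ``i`` (1 = null ... 4 = strong quantitative
    interaction), optionally with non-default prevalence or allocation.

    When ``q_a`` differs from 0.5 and ``q_b`` is not given, q_B is
    derived so the trial stays 1:1 overall.
    """
    try:
        (p1a, p0a, p1b, p0b), sensitive, null = _K2[i]
    except KeyError:
        raise ValueError(f"unknown K=2 scenario {i}; scenarios are 1-4") from None
    if q_b is None:
        q_b = 0.5 if q_a == 0.5 else balanced_q_b(pi_a, q_a)
    return Scenario(
        subsets=("A", "B"),
        pi=np.array([pi_a, 1.0 - pi_a]),
        q=np.array([q_a, q_b]),
        p1=np.array([p1a, p1b]),
        p0=np.array([p0a, p0b]),
        label=f"K2-scenario-{i}",
        null=null,
        sensitive=sensitive,
    )


def k3_scenario(i: int, pattern: int = 1) -> Scenario:
    """Built-in K=3 scenario ``i`` (1-7) under prevalence pattern 1-5."""
    try:
        (p1a, p0a, p1b, p0b, p1c, p0c), sensitive, null = _K3[i]
    except KeyError:
        raise ValueError(f"unknown K=3 scenario {i}; scenarios are 1-7") from None
    pi = np.array(k3_pattern(pattern))
    return Scenario(
        subsets=("A", "B", "C"),
        pi=pi,
        q=np.full(3, 0.5),
        p1=np.array([p1a, p1b, p1c]),
        p0=np.array([p0a, p0b, p0c]),
        label=f"K3-scenario-{i}-pattern-{pattern}",
        null=null,
        sensitive=sensitive,
    )
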