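"""Operating-characteristics tables, trajectories, and sensitivity sweeps.

Tables are the canonical output (tidy DataFrames with stable column
names); plots are optional artifacts generated from them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import Thresholds
from .posterior import BETA_UNIFORM_PRIOR, BetaParams
from .scenarios import balanced_q_b
from .simulate import (
    ENTIRE_POPULATION,
    OperatingCharacteristics,
    Scenario,
    TrialResult,
    canonical_outcomes,
    replicate,
)

__all__ = ["SweepSpec", "tabulate_decisions", "trajectory_table", "run_sweep", "oc_row"]


def oc_row(oc: OperatingCharacteristics) -> dict:
    """Flatten one OperatingCharacteristics into a table row."""
    row: dict = {"scenario": oc.scenario_label, "rule": oc.rule, "N": oc.N}
    row["go_entire_population"] = oc.proportion(ENTIRE_POPULATION)
    for outcome in canonical_outcomes(oc.subsets)[1:]:
        row[outcome] = oc.proportion(outcome)
    # any observed non-canonical outcome (e.g. enrichment of every subset)
    for outcome, p in oc.decision_proportions.items():
        if outcome not in row and outcome != ENTIRE_POPULATION:
            row[outcome] = p
    for lab in oc.subsets:
        row[f"mean_n_{lab}"] = oc.mean_n[lab]
    for lab in oc.subsets:
        row[f"bias_theta_{lab}"] = oc.mean_bias_theta[lab]
    row["false_positive"] = oc.false_positive_rate
    return row


def tabulate_decisions(ocs: Sequence[OperatingCharacteristics]) -> pd.DataFrame:
    """Decision table, one row per scenario x rule.

    Columns: the entire-population proportion, one enrichment-proportion
    column per terminal classification, per-subset mean sample sizes and
    biases, and the false positive rate. All OCs must share the sample
    size and analysis schedule.
    """
    if not ocs:
        raise ValueError("no operating characteristics given")
    schedules = {(oc.n_total, oc.n_analyses) for oc in ocs}
    if len(schedules) > 1:
        raise ValueError(f"mismatched schedules across OCs: {sorted(schedules)}")
    df = pd.DataFrame([oc_row(oc) for oc in ocs])
    prop_cols = [c for c in df.columns if c == "go_entire_population" or c.startswith("enrich:")]
    df[prop_cols] = df[prop_cols].fillna(0.0)
    sums = df[prop_cols].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise AssertionError(f"decision proportions do not sum to 1: {sums.tolist()}")
    return df


def trajectory_table(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Per-look decision trajectory over replications.

    For each analysis (interims then terminal): the proportion of
    replications already enriched by that look, the proportion still
    continuing in the entire population, and the mean cumulative
    enrollment per subset.
    """
    if not results:
        raise ValueError("no trial results given")
    subsets = results[0].subsets
    n_looks = len(results[0].looks)
    rows = []
    for look in range(n_looks):
        enriched = np.array(
            [r.enrichment_look is not None and r.enrichment_look <= look for r in results]
        )
        n_cum = np.mean([r.looks[look].n_cum for r in results], axis=0)
        row = {
            "look": look + 1,
            "analysis": "TA" if look == n_looks - 1 else f"IA{look + 1}",
            "prop_enriched": float(enriched.mean()),
            "prop_continuing": float(1.0 - enriched.mean()),
        }
        for lab, n in zip(subsets, n_cum):
            row[f"mean_cum_n_{lab}"] = float(n)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sensitivity sweep around a base scenario.

    ``vary`` is either "prevalence" (values are prevalences of the first
    subset) or "allocation" (values are experimental-arm fractions q in
    the first subset; the second subset's fraction is derived so the
    overall trial stays 1:1). Allocation sweeps require K = 2.
    """

    base_scenario: Scenario
    vary: str
    values: tuple[float, ...]
    thresholds: Thresholds
    N: int = 1000
    n_total: int = 800
    n_analyses: int = 4
    n_draws: int = 10_000
    prior: BetaParams = BETA_UNIFORM_PRIOR
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.vary not in ("prevalence", "allocation"):
            raise ValueError("vary must be 'prevalence' or 'allocation'")
        if not all(0 < v < 1 for v in self.values):
            raise ValueError("sweep values must lie in (0, 1)")
        if self.base_scenario.n_subsets != 2:
            raise ValueError("sweeps are defined for K=2 base scenarios")


def _swept_scenario(spec: SweepSpec, value: float) -> Scenario:
    sc = spec.base_scenario
    if spec.vary == "prevalence":
        return dc_replace(
            sc, pi=np.array([value, 1.0 - value]), label=f"{sc.label}-pi={value:g}"
        )
    pi_a = float(sc.pi[0])
    q_b = balanced_q_b(pi_a, value)  # raises naming the combination if infeasible
    return dc_replace(sc, q=np.array([value, q_b]), label=f"{sc.label}-qA={value:g}")


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Replicate the design at each sweep value and tabulate.

    Every sweep value reuses the same master seed, so the row at the
    base value is bitwise identical to a direct replicate of the base
    scenario.
    """
    ocs = []
    for v in spec.values:
        scenario = _swept_scenario(spec, v)
        oc = replicate(
            scenario,
            spec.thresholds,
            n_total=spec.n_total,
            n_analyses=spec.n_analyses,
            prior=spec.prior,
            n_draws=spec.n_draws,
            N=spec.N,
            master_seed=spec.seed,
            n_jobs=spec.n_jobs,
        )
        ocs.append(oc)
    df = tabulate_decisions(ocs)
    df.insert(0, spec.vary, list(spec.values))
    return df


def plot_trajectories(traj: pd.DataFrame, path: str) -> None:
    """Optional line plot of the per-look enrichment proportions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj["analysis"], traj["prop_enriched"], marker="o", label="enriched")
    ax.plot(traj["analysis"], traj["prop_continuing"], marker="s", label="entire population")
    ax.set_xlabel("analysis")
    ax.set_ylabel("proportion of replications")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sweep(df: pd.DataFrame, vary: str, columns: Sequence[str], path: str) -> None:
    """Optional line plot of decision proportions along a sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in columns:
        if col in df.columns:
            ax.plot(df[vary], df[col], marker="o", label=col)
    ax.set_xlabel(vary)
    ax.set_ylabel("proportion of replications")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
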