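"""Patient-level dataset handling and the sequential real-trial replay.

The replay mode applies the enrichment decision rules retrospectively
to an already-collected randomized trial: patients are taken in
enrollment order, analyses occur at fixed cumulative enrollment counts,
and once an enrichment fires only patients from the enriched subset(s)
are "enrolled" thereafter (others are skipped), with no further rule
evaluation. Per-look posterior estimates of dropped subsets stay frozen
at their enrichment-look values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import (
    EnrichmentState,
    Thresholds,
    evaluate_analysis,
    posterior_summaries,
    update_enrichment_state,
)
from .posterior import BETA_UNIFORM_PRIOR, BetaParams, SubsetArmCounts, sample_posterior
from .simulate import analysis_seed, enrich_label, seed_key

__all__ = ["TrialDataset", "AnalysisCalendar", "read_trial_csv", "analyze_trial"]


@dataclass(frozen=True)
class TrialDataset:
    """Validated patient-level trial data, sorted by enrollment order.

    ``frame`` holds one row per patient with columns ``id``, ``order``,
    ``arm`` (1 = experimental), ``outcome`` (1 = event) and one column
    per named biomarker partition.
    """

    frame: pd.DataFrame
    partitions: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset_labels(self, partition: str) -> tuple[str, ...]:
        if partition not in self.partitions:
            raise KeyError(f"unknown partition {partition!r}; have {self.partitions}")
        return tuple(sorted(self.frame[partition].unique()))


def read_trial_csv(
    path,
    id_col: str = "id",
    order_col: str = "enroll_order",
    arm_col: str = "arm",
    outcome_col: str = "outcome",
    partition_cols: Optional[Sequence[str]] = None,
) -> TrialDataset:
    """Read and validate a patient-level CSV export.

    Any column beyond the id/order/arm/outcome ones is treated as a
    biomarker partition unless ``partition_cols`` is given. The order
    column may hold integers or parseable dates; records are sorted by
    it (stably, so file order breaks ties).
    """
    df = pd.read_csv(path)
    required = [id_col, order_col, arm_col, outcome_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if partition_cols is None:
        partition_cols = [c for c in df.columns if c not in required]
    else:
        absent = [c for c in partition_cols if c not in df.columns]
        if absent:
            raise ValueError(f"partition columns not in file: {absent}")
    if not partition_cols:
        raise ValueError("no biomarker partition column found")

    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate patient ids: {dupes[:5]}")
    for col in (arm_col, outcome_col):
        bad = df[~df[col].isin([0, 1])]
        if not bad.empty:
            row = bad.index[0]
            raise ValueError(
                f"non-binary value {bad[col].iloc[0]!r} in column {col!r} at row {row}"
            )
    for col in partition_cols:
        if df[col].isna().any():
            row = df[df[col].isna()].index[0]
            raise ValueError(f"missing subset label in partition {col!r} at row {row}")

    order = df[order_col]
    if not pd.api.types.is_numeric_dtype(order):
        order = pd.to_datetime(order)
    df = df.assign(_order=order).sort_values("_order", kind="mergesort").drop(columns="_order")
    out = df.rename(
        columns={id_col: "id", order_col: "order", arm_col: "arm", outcome_col: "outcome"}
    ).reset_index(drop=True)
    out["arm"] = out["arm"].astype(int)
    out["outcome"] = out["outcome"].astype(int)
    return TrialDataset(frame=out, partitions=tuple(partition_cols))


@dataclass(frozen=True)
class AnalysisCalendar:
    """Cumulative enrolled-patient counts at which analyses occur."""

    looks: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "looks", tuple(int(x) for x in self.looks))
        if not self.looks:
            raise ValueError("at least one analysis required")
        if any(x <= 0 for x in self.looks) or any(
            b <= a for a, b in zip(self.looks, self.looks[1:])
        ):
            raise ValueError("looks must be strictly increasing positive counts")

    @classmethod
    def equal_spacing(cls, n_total: int, n_analyses: int) -> "AnalysisCalendar":
        if n_total % n_analyses != 0:
            raise ValueError("n_total must be a multiple of n_analyses")
        seg = n_total // n_analyses
        return cls(tuple(seg * (i + 1) for i in range(n_analyses)))


def analyze_trial(
    dataset: TrialDataset,
    partition: str,
    calendar: AnalysisCalendar,
    thresholds: Thresholds,
    prior: BetaParams = BETA_UNIFORM_PRIOR,
    n_draws: int = 10_000,
    seed=0,
) -> pd.DataFrame:
    """Replay the sequential enrichment rules on a real dataset.

    Returns one row per analysis with cumulative per-subset enrollment,
    posterior mean and 95% credibility interval of the global and
    per-subset relative risks, the influence probabilities, the
    applicable interaction probabilities, and the decision.
    """
    labels = dataset.subset_labels(partition)
    if calendar.looks[-1] > dataset.n:
        raise ValueError(
            f"calendar requires {calendar.looks[-1]} patients but dataset has {dataset.n}"
        )
    frame = dataset.frame
    subset_of = frame[partition].to_numpy()
    arms = frame["arm"].to_numpy()
    outcomes = frame["outcome"].to_numpy()
    lab_index = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)

    key = seed_key(seed)
    state = EnrichmentState(active=labels, frozen=False)
    events = np.zeros((2, K), dtype=np.int64)
    totals = np.zeros((2, K), dtype=np.int64)
    frozen_estimates: dict[str, dict] = {}
    pointer = 0
    accepted = 0
    rows = []
    n_looks = len(calendar.looks)

    for look, target in enumerate(calendar.looks):
        while accepted < target and pointer < len(frame):
            lab = subset_of[pointer]
            if lab in state.active:
                k = lab_index[lab]
                j = arms[pointer]
                totals[j, k] += 1
                events[j, k] += outcomes[pointer]
                accepted += 1
            pointer += 1

        counts = SubsetArmCounts(labels, events.copy(), totals.copy())
        look_seed = analysis_seed(key, look)
        decision = None
        if not state.frozen and len(state.active) >= 2:
            decision = evaluate_analysis(
                counts, state.active, thresholds, prior=prior, n_draws=n_draws, seed=look_seed
            )
            new_state = update_enrichment_state(state, decision)
            if new_state.frozen:
                # freeze dropped subsets' estimates at this look's values
                dropped = set(state.active) - set(new_state.active)
                full = posterior_summaries(
                    sample_posterior(counts, prior=prior, n_draws=n_draws, seed=look_seed)
                )
                for lab in dropped:
                    frozen_estimates[lab] = full[lab]
            state = new_state

        summaries = posterior_summaries(
            sample_posterior(counts, prior=prior, n_draws=n_draws, seed=look_seed)
        )
        summaries.update(frozen_estimates)

        row: dict = {
            "look": look + 1,
            "analysis": "TA" if look == n_looks - 1 else f"IA{look + 1}",
            "n_enrolled": accepted,
        }
        for lab in labels:
            row[f"n_{lab}"] = int(totals[:, lab_index[lab]].sum())
        g = summaries["__global__"]
        row.update(theta_global=g["mean"], theta_global_lo=g["lo"], theta_global_hi=g["hi"])
        for lab in labels:
            s = summaries[lab]
            row[f"theta_{lab}"] = s["mean"]
            row[f"theta_{lab}_lo"] = s["lo"]
            row[f"theta_{lab}_hi"] = s["hi"]
        if decision is not None:
            for lab, ev in decision.per_subset_evidence.items():
                row[f"p1_{lab}"] = ev["p1"]
            if decision.interaction is not None:
                if decision.interaction.p2 is not None:
                    for lab, p2 in decision.interaction.p2.items():
                        row[f"p2_{lab}"] = p2
                row["p_quali"] = decision.interaction.p_quali
                row["p_quanti"] = decision.interaction.p_quanti
            row["decision"] = (
                enrich_label(decision.enriched_subsets)
                if decision.action == "enrich"
                else "go_with_entire_population"
            )
        else:
            row["decision"] = (
                enrich_label(state.active) + " (frozen)"
                if state.frozen
                else "go_with_entire_population"
            )
        rows.append(row)

    return pd.DataFrame(rows)
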