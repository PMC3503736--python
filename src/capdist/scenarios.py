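"""Closure, capacity-transfer and optimal-rebalancing experiments.

A scenario is a set of capacity overrides (closure = capacity 0, doubling =
2x the current capacity).  Running a scenario re-allocates every patient
under the capacity-distance mechanism with the overridden capacities and
reports equity statistics: Gini coefficient, long-commute threshold counts
and time summaries, overall and by urban/rural stratum.  Scenario results
are pure functions of (matrix, capacities, scenario); the baseline is never
mutated.

Note the round mechanism is not monotone: closing a facility can *shorten*
an individual patient's commute by re-timing proposal rounds, even though
aggregate equity typically worsens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import (
    AssignmentResult,
    InfeasibleError,
    allocate_capacity_distance,
    allocate_distance,
)
from .equity import DEFAULT_THRESHOLDS, TimeSummary, gini, summarize_times, threshold_counts
from .network import TravelTimeMatrix

__all__ = [
    "Scenario",
    "ScenarioResult",
    "OptimalCapacityReport",
    "apply_scenario",
    "run_scenarios",
    "optimal_capacity",
]


@dataclass(frozen=True)
class Scenario:
    """Named capacity overrides, ``facility_id -> new capacity``."""

    name: str
    capacity_overrides: Mapping[str, int] = field(default_factory=dict)

    @classmethod
    def closure(cls, name: str, facility_ids: Sequence[str]) -> "Scenario":
        """Close facilities by setting their capacity to zero."""
        return cls(name, {f: 0 for f in facility_ids})

    @classmethod
    def transfer(
        cls,
        name: str,
        close: Sequence[str],
        double: Sequence[str],
        capacities: Mapping[str, int],
    ) -> "Scenario":
        """Close one facility group and double the capacity of another."""
        overrides = {f: 0 for f in close}
        overrides.update({f: 2 * int(capacities[f]) for f in double})
        return cls(name, overrides)


def apply_scenario(
    capacities: Mapping[str, int], scenario: Scenario
) -> tuple[dict[str, int], int]:
    """Apply capacity overrides; returns (new capacities, signed total
    capacity change).  Untouched facilities are unchanged."""
    unknown = [f for f in scenario.capacity_overrides if f not in capacities]
    if unknown:
        raise KeyError(f"scenario overrides unknown facilities: {unknown}")
    if any(v < 0 for v in scenario.capacity_overrides.values()):
        raise ValueError("overridden capacities must be non-negative")
    new = {f: int(c) for f, c in capacities.items()}
    new.update({f: int(c) for f, c in scenario.capacity_overrides.items()})
    delta = sum(new.values()) - sum(int(c) for c in capacities.values())
    return new, delta


@dataclass(frozen=True)
class ScenarioResult:
    """Equity outcome of one capacity configuration."""

    name: str
    capacity_delta: int
    gini: float | None
    threshold_counts: dict[float, int] | None
    summary_overall: TimeSummary | None
    summary_by_stratum: dict[str, TimeSummary] | None
    assignment: AssignmentResult | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _run_one(
    matrix: TravelTimeMatrix,
    capacities: Mapping[str, int],
    scenario: Scenario,
    strata: Mapping[str, str] | None,
    thresholds: Sequence[float],
) -> ScenarioResult:
    new_caps, delta = apply_scenario(capacities, scenario)
    try:
        result = allocate_capacity_distance(matrix, new_caps)
    except InfeasibleError as exc:
        return ScenarioResult(
            name=scenario.name, capacity_delta=delta, gini=None,
            threshold_counts=None, summary_overall=None, summary_by_stratum=None,
            assignment=None, error=str(exc),
        )
    times = result.time.to_numpy(dtype=float)
    by_stratum = None
    if strata is not None:
        labels = result.table.index.map(strata)
        by_stratum = {
            s: summarize_times(times[labels == s])
            for s in sorted(set(labels))
        }
    return ScenarioResult(
        name=scenario.name,
        capacity_delta=delta,
        gini=gini(times),
        threshold_counts=threshold_counts(times, thresholds),
        summary_overall=summarize_times(times),
        summary_by_stratum=by_stratum,
        assignment=result,
    )


def run_scenarios(
    matrix: TravelTimeMatrix,
    capacities: Mapping[str, int],
    scenarios: Sequence[Scenario],
    strata: Mapping[str, str] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    baseline_name: str = "No closure",
) -> list[ScenarioResult]:
    """Run a list of scenarios against a common baseline.

    The baseline (no overrides) is always evaluated first.  An infeasible
    scenario yields a :class:`ScenarioResult` carrying an error message;
    the remaining scenarios still run.
    """
    todo = [Scenario(baseline_name, {})] + list(scenarios)
    return [_run_one(matrix, capacities, s, strata, thresholds) for s in todo]


@dataclass(frozen=True)
class OptimalCapacityReport:
    """Rebalancing toward the zero-waste system in which every patient
    attends their nearest facility and every facility is exactly full.

    Target capacity per facility equals its nearest-facility demand.
    Reducers are facilities whose demand is below current capacity;
    increasers those whose demand exceeds it.
    """

    target_capacity: dict[str, int]
    n_facilities: int
    n_reducers: int
    reducers_old_capacity: int
    reducers_new_capacity: int
    n_increasers: int
    increasers_old_capacity: int
    increasers_new_capacity: int

    @property
    def reducer_share(self) -> float:
        return self.n_reducers / self.n_facilities

    @property
    def increaser_share(self) -> float:
        return self.n_increasers / self.n_facilities

    @property
    def reducer_capacity_ratio(self) -> float:
        return self.reducers_new_capacity / self.reducers_old_capacity

    @property
    def increaser_capacity_ratio(self) -> float:
        return self.increasers_new_capacity / self.increasers_old_capacity


def optimal_capacity(
    matrix: TravelTimeMatrix, capacities: Mapping[str, int]
) -> OptimalCapacityReport:
    """Set every facility's target capacity to its nearest-facility demand.

    After applying the targets, a fresh capacity-distance allocation sends
    every patient to their nearest facility and fills every facility exactly
    (the rebalanced system is a fixed point of the mechanism).
    """
    demand = (
        allocate_distance(matrix)
        .facility_counts()
        .reindex(list(matrix.facility_ids))
        .fillna(0)
        .astype(int)
    )
    target = {f: int(demand[f]) for f in matrix.facility_ids}
    capv = pd.Series({f: int(capacities[f]) for f in matrix.facility_ids})
    reducers = demand.index[demand < capv]
    increasers = demand.index[demand > capv]
    return OptimalCapacityReport(
        target_capacity=target,
        n_facilities=len(capv),
        n_reducers=len(reducers),
        reducers_old_capacity=int(capv[reducers].sum()),
        reducers_new_capacity=int(demand[reducers].sum()),
        n_increasers=len(increasers),
        increasers_old_capacity=int(capv[increasers].sum()),
        increasers_new_capacity=int(demand[increasers].sum()),
    )
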