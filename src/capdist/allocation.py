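"""Patient-to-facility assignment under two behavioural models.

The *distance model* sends every patient to their minimum-travel-time
facility, ignoring capacity.  The *capacity-distance model* respects
facility capacity through a round-based mechanism: in each round every
still-unassigned patient proposes to their nearest facility with remaining
capacity, and each facility accepts its proposers in ascending travel time
until its remaining capacity is exhausted.  Accepted patients are fixed
permanently; rejected patients try their next-nearest open facility in the
following round, until everyone is placed.

The mechanism is behavioural, not optimal: it mimics patients sequentially
seeking the closest available dialysis slot, and it is deliberately *not*
equivalent to a global transportation-problem optimum.

Tie-breaks are fully specified so results are deterministic: equal-time
facilities are taken in ascending facility_id, equal-time proposers in
ascending patient_id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .network import TravelTimeMatrix

__all__ = [
    "AssignmentResult",
    "LoadSummary",
    "InfeasibleError",
    "allocate_distance",
    "allocate_capacity_distance",
    "facility_rank",
    "gap_table",
    "GapTable",
    "load_summary",
]


class InfeasibleError(ValueError):
    """Total capacity is below the number of patients."""


@dataclass(frozen=True)
class AssignmentResult:
    """Per-patient assignment with travel time, proximity rank and round.

    ``table`` is indexed by patient_id with columns ``facility_id``,
    ``time_min``, ``rank`` (1 = nearest facility overall) and ``round``
    (acceptance round; 1 for the distance model).  Unassigned patients (only
    possible in the opt-in partial mode) carry NA facility/time/round.
    """

    model: str  # "distance" | "capacity_distance"
    table: pd.DataFrame
    n_rounds: int

    @property
    def assignment(self) -> pd.Series:
        return self.table["facility_id"]

    @property
    def time(self) -> pd.Series:
        return self.table["time_min"]

    @property
    def rank(self) -> pd.Series:
        return self.table["rank"]

    @property
    def unassigned(self) -> list[str]:
        return list(self.table.index[self.table["facility_id"].isna()])

    def facility_counts(self) -> pd.Series:
        return self.table["facility_id"].dropna().value_counts()


def _order_columns(matrix: TravelTimeMatrix) -> np.ndarray:
    """Column permutation sorting facilities by ascending facility_id."""
    return np.argsort(np.asarray(matrix.facility_ids, dtype=object), kind="stable")


def _ranks(times: np.ndarray, chosen: np.ndarray) -> np.ndarray:
    """Proximity rank of the chosen facility per row: 1 + number of
    strictly closer facilities (equidistant facilities share the rank)."""
    chosen_t = times[np.arange(len(chosen)), chosen]
    return 1 + (times < chosen_t[:, None]).sum(axis=1)


def allocate_distance(matrix: TravelTimeMatrix) -> AssignmentResult:
    """Assign every patient to their minimum-time facility (capacity
    ignored); travel-time ties go to the lower facility_id."""
    t = matrix.times
    if t.size == 0:
        raise ValueError("empty travel-time matrix")
    col_order = _order_columns(matrix)
    sorted_t = t[:, col_order]
    best_sorted = np.argmin(sorted_t, axis=1)  # first min <=> lowest facility_id
    best = col_order[best_sorted]
    fids = np.asarray(matrix.facility_ids, dtype=object)
    table = pd.DataFrame(
        {
            "facility_id": fids[best],
            "time_min": t[np.arange(len(best)), best],
            "rank": _ranks(t, best),
            "round": np.ones(len(best), dtype=np.int64),
        },
        index=pd.Index(matrix.patient_ids, name="patient_id"),
    )
    return AssignmentResult(model="distance", table=table, n_rounds=1)


def allocate_capacity_distance(
    matrix: TravelTimeMatrix,
    capacities: Mapping[str, int],
    allow_unassigned: bool = False,
) -> AssignmentResult:
    """Round-based capacity-constrained assignment.

    Each round, unassigned patients propose to their nearest facility with
    remaining capacity; facilities accept proposers in ascending travel time
    (ties by patient_id) up to remaining capacity; accepted patients are
    never displaced.  Raises :class:`InfeasibleError` when total capacity is
    below the number of patients, unless ``allow_unassigned`` is set, in
    which case leftover patients are flagged with NA assignments.
    """
    t = matrix.times
    n_p, n_f = t.shape
    fids = list(matrix.facility_ids)
    pids = list(matrix.patient_ids)
    missing = [f for f in fids if f not in capacities]
    if missing:
        raise KeyError(f"capacities missing for facilities: {missing}")
    remaining = np.array([int(capacities[f]) for f in fids], dtype=np.int64)
    if (remaining < 0).any():
        raise ValueError("capacities must be non-negative")
    if remaining.sum() < n_p and not allow_unassigned:
        raise InfeasibleError(
            f"total capacity {int(remaining.sum())} < {n_p} patients; "
            "pass allow_unassigned=True to flag the excess instead"
        )

    # per-patient preference order: ascending time, ties by facility_id
    fid_rank = np.empty(n_f, dtype=np.int64)
    fid_rank[_order_columns(matrix)] = np.arange(n_f)
    pref = np.lexsort((np.broadcast_to(fid_rank, t.shape), t), axis=1)
    ptr = np.zeros(n_p, dtype=np.int64)  # next preference index to try

    pid_rank = np.empty(n_p, dtype=np.int64)
    pid_rank[np.argsort(np.asarray(pids, dtype=object), kind="stable")] = np.arange(n_p)

    assigned = np.full(n_p, -1, dtype=np.int64)
    accept_round = np.zeros(n_p, dtype=np.int64)
    unassigned = np.arange(n_p)
    round_no = 0
    while len(unassigned) and remaining.sum() > 0:
        round_no += 1
        # advance each pointer past full facilities (they can never reopen)
        proposals_to = np.empty(len(unassigned), dtype=np.int64)
        for k, p in enumerate(unassigned):
            while remaining[pref[p, ptr[p]]] == 0:
                ptr[p] += 1
            proposals_to[k] = pref[p, ptr[p]]
        for f in np.unique(proposals_to):
            props = unassigned[proposals_to == f]
            order = np.lexsort((pid_rank[props], t[props, f]))
            take = props[order][: remaining[f]]
            assigned[take] = f
            accept_round[take] = round_no
            remaining[f] -= len(take)
        unassigned = unassigned[assigned[unassigned] < 0]

    idx = pd.Index(pids, name="patient_id")
    ok = assigned >= 0
    fid_arr = np.asarray(fids, dtype=object)
    table = pd.DataFrame(
        {
            "facility_id": np.where(ok, fid_arr[np.maximum(assigned, 0)], None),
            "time_min": np.where(ok, t[np.arange(n_p), np.maximum(assigned, 0)], np.nan),
            "rank": pd.array(
                np.where(ok, _ranks(t, np.maximum(assigned, 0)), 0), dtype="Int64"
            ),
            "round": pd.array(np.where(ok, accept_round, 0), dtype="Int64"),
        },
        index=idx,
    )
    table.loc[~ok, ["rank", "round"]] = pd.NA
    return AssignmentResult(model="capacity_distance", table=table, n_rounds=round_no)


def facility_rank(matrix: TravelTimeMatrix, patient_id: str, facility_id: str) -> int:
    """Proximity rank of a facility for a patient: 1 + number of facilities
    strictly closer; equidistant facilities share the better rank."""
    i = matrix.patient_ids.index(patient_id)
    j = matrix.facility_ids.index(facility_id)
    return int(1 + (matrix.times[i] < matrix.times[i, j]).sum())


@dataclass(frozen=True)
class GapTable:
    """Per-proximity-rank summary of the commuting-time gap between the
    capacity-distance and distance models."""

    table: pd.DataFrame  # index: rank; columns: n, gap_median, gap_q25, gap_q75
    n_patients: int
    n_non_nearest: int  # patients with capacity-model proximity rank >= 2

    @property
    def share_non_nearest(self) -> float:
        return self.n_non_nearest / self.n_patients


def gap_table(distance: AssignmentResult, capdist: AssignmentResult) -> GapTable:
    """Summarise, per capacity-model proximity rank, the time penalty of the
    capacity constraint relative to the free nearest-facility choice."""
    if not distance.table.index.equals(capdist.table.index):
        raise ValueError("results cover different patients")
    gap = capdist.time - distance.time
    df = pd.DataFrame({"rank": capdist.rank.astype("Int64"), "gap": gap}).dropna()
    grouped = df.groupby("rank")["gap"]
    table = pd.DataFrame(
        {
            "n": grouped.size(),
            "gap_median": grouped.median(),
            "gap_q25": grouped.quantile(0.25),
            "gap_q75": grouped.quantile(0.75),
        }
    )
    n_non_nearest = int((df["rank"] >= 2).sum())
    return GapTable(table=table, n_patients=len(df), n_non_nearest=n_non_nearest)


@dataclass(frozen=True)
class LoadSummary:
    """Facility load accounting under free nearest-facility demand.

    ``per_facility`` has columns capacity, demand (distance-model nearest
    counts), assigned (capacity-distance counts), excess = max(0, demand -
    capacity) and slack = max(0, capacity - demand).  Aggregates summarise
    excess over overloaded facilities and slack over underloaded ones.
    """

    per_facility: pd.DataFrame
    n_overloaded: int
    overloaded_capacity: int
    excess_median: float
    excess_range: tuple[int, int]
    excess_total: int
    n_underloaded: int
    underloaded_capacity: int
    slack_median: float
    slack_range: tuple[int, int]
    slack_total: int


def load_summary(matrix: TravelTimeMatrix, capacities: Mapping[str, int]) -> LoadSummary:
    """Compare nearest-facility demand with capacity per facility.

    The conservation identity ``slack_total - excess_total ==
    total_capacity - n_patients`` holds on every input.
    """
    dist = allocate_distance(matrix)
    cap = allocate_capacity_distance(matrix, capacities, allow_unassigned=True)
    fids = list(matrix.facility_ids)
    demand = dist.facility_counts().reindex(fids).fillna(0).astype(int)
    assigned = cap.facility_counts().reindex(fids).fillna(0).astype(int)
    capv = pd.Series({f: int(capacities[f]) for f in fids})
    excess = (demand - capv).clip(lower=0)
    slack = (capv - demand).clip(lower=0)
    per_facility = pd.DataFrame(
        {
            "capacity": capv,
            "demand": demand,
            "assigned": assigned,
            "excess": excess,
            "slack": slack,
        }
    )
    per_facility.index.name = "facility_id"
    over = per_facility[per_facility["excess"] > 0]
    under = per_facility[per_facility["slack"] > 0]

    def _rng(s: pd.Series) -> tuple[int, int]:
        return (int(s.min()), int(s.max())) if len(s) else (0, 0)

    return LoadSummary(
        per_facility=per_facility,
        n_overloaded=len(over),
        overloaded_capacity=int(over["capacity"].sum()),
        excess_median=float(over["excess"].median()) if len(over) else 0.0,
        excess_range=_rng(over["excess"]),
        excess_total=int(excess.sum()),
        n_underloaded=len(under),
        underloaded_capacity=int(under["capacity"].sum()),
        slack_median=float(under["slack"].median()) if len(under) else 0.0,
        slack_range=_rng(under["slack"]),
        slack_total=int(slack.sum()),
    )
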