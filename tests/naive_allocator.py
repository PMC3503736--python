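"""Deliberately naive reference implementation of the round-based
capacity-constrained assignment, used only as an independent oracle.

Transcribes the mechanism literally with plain dicts and sorts and shares
no code with the production allocator: every round, each unassigned patient
proposes to the nearest facility that still has a free slot (ties by
facility id); each facility accepts its proposers in ascending travel time
(ties by patient id) up to its remaining capacity; accepted patients are
final.
"""

from __future__ import annotations


def naive_capacity_distance(
    times: dict[str, dict[str, float]], capacities: dict[str, int]
) -> dict[str, str]:
    """Return patient -> facility under the literal round mechanism."""
    remaining = {f: int(c) for f, c in capacities.items()}
    if sum(remaining.values()) < len(times):
        raise ValueError("infeasible: total capacity below patient count")
    assigned: dict[str, str] = {}
    while len(assigned) < len(times):
        proposals: dict[str, list[str]] = {}
        for p in sorted(times):
            if p in assigned:
                continue
            open_facilities = [f for f in times[p] if remaining[f] > 0]
            target = min(open_facilities, key=lambda f: (times[p][f], f))
            proposals.setdefault(target, []).append(p)
        for f, proposers in proposals.items():
            proposers.sort(key=lambda p: (times[p][f], p))
            for p in proposers[: remaining[f]]:
                assigned[p] = f
            remaining[f] -= min(len(proposers), remaining[f])
    return assigned


def naive_distance(times: dict[str, dict[str, float]]) -> dict[str, str]:
    """Patient -> nearest facility, ties by facility id."""
    return {p: min(row, key=lambda f: (row[f], f)) for p, row in times.items()}
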