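"""Closure, capacity-transfer and optimal-rebalancing experiments.

Closing a facility sets its capacity to zero and re-runs the
capacity-distance allocation; a transfer simultaneously closes one group
and doubles another.  The optimal rebalancing sets every facility's
capacity to its nearest-facility demand, so all patients attend their
nearest facility and every facility is exactly full.
"""

from capdist import (
    PRESETS, Scenario, classify_urban_rural, generate_network, generate_region,
    optimal_capacity, patient_strata, relative_change, run_scenarios,
    travel_time_matrix,
)

region = generate_region(PRESETS["hiroshima"].replace(seed=1))
network = generate_network(region, seed=1)
matrix = travel_time_matrix(network, region.patients, region.facilities)
caps = region.capacities()
strata = patient_strata(region, classify_urban_rural(region))

# close the three largest facilities, then transfer their capacity to the
# three smallest instead of closing them outright
by_cap = region.facilities.sort_values("capacity")
largest = list(by_cap["facility_id"].tail(3))
smallest = list(by_cap["facility_id"].head(3))
scenarios = [
    Scenario.closure("close 3 largest", largest),
    Scenario.transfer("shift to 3 smallest", close=largest, double=smallest,
                      capacities=caps),
]
results = run_scenarios(matrix, caps, scenarios, strata=strata)
base = results[0]
print(f"{'scenario':<22} {'dCap':>6} {'Gini':>6} {'change':>7} {'>60min':>7}")
for r in results:
    change = relative_change(base.gini, r.gini)
    print(f"{r.name:<22} {r.capacity_delta:>+6d} {r.gini:>6.3f} "
          f"{change:>+6.0f}% {r.threshold_counts[60.0]:>7d}")

opt = optimal_capacity(matrix, caps)
print(
    f"optimal rebalancing: {100 * opt.reducer_share:.0f}% of facilities shrink "
    f"to {opt.reducer_capacity_ratio:.2f}x capacity, "
    f"{100 * opt.increaser_share:.0f}% grow to "
    f"{opt.increaser_capacity_ratio:.2f}x"
)
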