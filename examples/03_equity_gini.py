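"""Equity of commuting times: Lorenz curve, Gini and urban-rural contrast.

Patients are ranked by commuting time; the Lorenz curve plots the
cumulative share of total commuting time against the cumulative share of
patients, and the Gini coefficient is twice the area between the curve and
the diagonal (0 = complete equity).
"""

import numpy as np

from capdist import (
    PRESETS, allocate_capacity_distance, classify_urban_rural, generate_network,
    generate_region, gini, lorenz, patient_strata, rank_sum_test,
    threshold_counts, travel_time_matrix,
)

region = generate_region(PRESETS["hiroshima"].replace(seed=1))
network = generate_network(region, seed=1)
matrix = travel_time_matrix(network, region.patients, region.facilities)
cap = allocate_capacity_distance(matrix, region.capacities())
times = cap.time.to_numpy(float)

print(f"Gini coefficient (capacity-distance model): {gini(times):.3f}")
curve = lorenz(times)
half = curve.points[len(times) // 2]
print(f"the worst-off half of patients carries "
      f"{100 * (1 - half[1]):.0f}% of total commuting time")
print("patients commuting longer than 30/45/60/90 min:",
      list(threshold_counts(times).values()))

strata = patient_strata(region, classify_urban_rural(region))
labels = cap.table.index.map(strata)
rural, urban = times[labels == "rural"], times[labels == "urban"]
test = rank_sum_test(rural, urban)
print(f"median commute rural {np.median(rural):.1f} vs urban "
      f"{np.median(urban):.1f} min (Mann-Whitney p = {test.p:.2g})")
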