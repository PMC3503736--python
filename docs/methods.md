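# Methods

## Allocation mechanisms

Both models operate on a patient-by-facility travel-time matrix `t` in
minutes.

**Distance model.** Each patient attends the facility minimising `t[p, f]`.
Ties are broken toward the lower facility id so results are deterministic.

**Capacity-distance model.** Facilities carry a hard capacity (maximum
outpatient count, set in practice by consoles and staffing). The mechanism
runs in rounds: (a) every unassigned patient proposes to the nearest
facility with remaining capacity (full facilities are skipped rather than
"rejecting", which is equivalent to trying the next-nearest facility and
simpler to state); (b) each facility accepts its current-round proposers in
ascending travel time up to its remaining capacity; (c) accepted patients
are fixed permanently and remaining capacity decreases. Each round assigns
at least one patient, so the procedure terminates in at most `n_patients`
rounds. Travel-time ties among proposers go to the lower patient id and
equal-time facilities to the lower facility id; with those rules the output
is a pure, platform-independent function of `(t, capacities)`.

Two properties deserve emphasis. First, acceptance is *final*: a facility
never bumps an accepted patient for a closer one who arrives in a later
round. The mechanism therefore differs from deferred acceptance with
displacement and from processing all `(patient, facility)` pairs in one
global ascending-time sweep; it models patients sequentially claiming the
closest open slot. Second, it is *not monotone*: closing a facility can
shorten an individual commute, because the closure can re-time a patient's
proposal into an earlier round where they outcompete someone else. A
four-patient counterexample exhibiting this is kept as a regression test so
the mechanism is never "optimised" into a transportation-problem solution,
which would be a different model. If total capacity is below the patient
count the allocator raises an error by default; an explicit opt-in leaves
the excess patients unassigned and flagged.

**Proximity rank** of an assignment is 1 plus the number of facilities
strictly closer to the patient; equidistant facilities share the better
rank. The gap table groups patients by the rank of their capacity-model
facility and summarises the per-patient time penalty relative to the
distance model.

**Load accounting.** Under the distance model, facility demand is the
nearest-patient count; `excess = max(0, demand - capacity)` and
`slack = max(0, capacity - demand)` satisfy the conservation identity
`total slack - total excess = total capacity - total patients` on every
input, which the tests assert on random instances.

**Optimal rebalancing** sets every facility's capacity to its distance-model
demand. Re-running the capacity-distance allocation then sends every
patient to a nearest facility and fills every facility exactly — a fixed
point of the mechanism, verified as a property test.

## Equity metrics

The Gini coefficient is computed from the Lorenz polyline exactly as the
geometric definition states: patients sorted by time, point `k` at
`(k/n, (sum of k smallest)/total)`, trapezoidal area, `G = 1 - 2A`. This is
algebraically identical to `sum_ij |t_i - t_j| / (2 n^2 mean)`, and the test
suite keeps both routes and requires agreement to 1e-12. No finite-sample
`n/(n-1)` correction is applied. Zero commuting times are legal
observations (a patient can live next to their facility) and enter the
Gini; only an all-zero vector is rejected as degenerate. Threshold counts
("longer than 30/45/60/90 minutes") use strict inequality. Group contrasts
use the Mann-Whitney rank-sum test, two-sided, exact when both groups have
n ≤ 8 and the pooled sample is tie-free, otherwise the normal approximation
with tie and continuity corrections (via `scipy.stats.mannwhitneyu`).

Quantiles everywhere (block summaries, time summaries, gap tables) use
linear interpolation between order statistics (numpy's default, "type 7").
Minutes are stored at full precision and rendered at 2 decimals only in
reports; Gini at 3 decimals.

## Synthetic regions

Real dialysis registries are confidential, so study regions are generated
synthetically. The default (`hiroshima` preset) targets the scale of a
prefecture of 2,876,642 residents in 1,867 census blocks with 98 facilities
of total capacity 8,643 and a dialysis prevalence of 256.36 per 100,000
(≈ 7,374 expected patients).

- **Blocks.** Log population density is normal with median 770 /km² and
  sigma 2.0. Log area couples negatively to density
  (`d log area / d log density = -0.7`, residual sigma 1.0, median area
  1 km² at the median density), so rural blocks are large and sparse.
  Populations are density × area rescaled to the exact population target
  (largest block absorbs the rounding remainder). Block centroids follow a
  monocentric layout: denser blocks sit nearer the regional centre of a
  disc whose area matches the summed block areas, with radial jitter.
- **Patients.** Per block, Binomial(population, prevalence); locations
  uniform in a disc of the block's area around its centroid (a stand-in for
  address-level geocoding, which is out of scope).
- **Urban/rural partition.** Blocks sorted by ascending density (ties by
  block id); rural is the shortest prefix whose cumulative patient count
  reaches the target share (default 25%). "At least 25%" with a minimal
  prefix keeps the rural share tight; the overshoot is at most one block's
  patients.
- **Facilities.** Placed in blocks with probability proportional to
  population^1.2 (mild urban concentration), positioned within the block
  disc. Capacities are log-normal by the stratum of the home block
  (medians 76 urban / 34 rural, sigma 0.8, clipped to [5, 650] — the
  dispersion and bounds are invented plumbing), then rescaled-and-rounded
  to the total-capacity target with the remainder on the largest facility.
  A capacity target below the expected patient count is rejected as an
  infeasible configuration.

**Road network.** A grid with spacing 2 km spans the region's bounding box;
edges draw a speed class from a configurable table (default five classes:
highway 80, major 60, arterial 50, collector 40, local 30 km/h — any
number of classes is supported), the central cross-axes form high-speed
corridors, and diagonal shortcuts appear with probability 0.05. Patients
and facilities snap to the nearest node (no partial-edge access legs);
entry `t[p, f]` is the shortest-path sum of `60·length/speed` between the
snapped nodes, computed with `scipy.sparse.csgraph.dijkstra`. Times are
symmetric and one-way; externally supplied (possibly asymmetric) matrices
are accepted through the CSV loader. Distances are planar Euclidean on
projected km coordinates — no geodesy, turn restrictions, congestion or
public transport.

## What the synthetic data does and does not emulate

The generator reproduces *marginal* structure: block-density and area
distributions, stratified block summaries, patient totals, facility count
and capacity mass, and the urban/rural patient split. At the default scale
the pipeline also reproduces the qualitative capacity phenomena: roughly
half the facilities are over-subscribed under free nearest-facility choice,
about a third of patients are displaced from their nearest facility by
capacity limits, the capacity model raises the commuting-time Gini, and the
optimal rebalancing shrinks about half the facilities to roughly a third of
their capacity while the other half roughly doubles.

It does **not** reproduce real geography. In particular, the monocentric
disc has no isolated rural valleys or coastal peninsulas, so rural patients
usually have a second facility within moderate reach; closure experiments
at default settings therefore produce much smaller equity shifts than a
real region with topographically isolated rural hubs would show. Passing
tests demonstrate the correctness and invariances of the mechanisms, not
the magnitude of closure effects in any real prefecture. The closure
scenario machinery itself is exercised end-to-end (feasibility preserved,
per-scenario errors isolated, purity under repetition).

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configuration and seed give bit-identical tables, files and reports.
- The acceptance pipeline and the test suite run at full study scale
  (≈ 7,400 patients × 98 facilities, ≈ 3,700 network nodes), which takes a
  few seconds; property suites use 1,000 random small instances
  (≤ 12 patients, ≤ 5 facilities) against an independently written naive
  transcription of the round mechanism.
- Degenerate inputs are rejected loudly: empty matrices, all-zero time
  vectors, regions without patients, infeasible capacity totals, malformed
  matrix CSV cells (errors name the offending patient and facility).
- Facility "consoles" are carried as an informational field (≈ capacity /
  3.6) and play no role in allocation.

## Known limitations

- Patient choice is travel time only; preference factors (working status,
  family support, clinical complexity) are out of scope, as is any
  facility-side selection of patients.
- No facility-opening or siting optimisation; closures, capacity transfers
  and demand-matching rebalancing only.
- The urban/rural cutoff density emerges from the generated density
  distribution (≈ 660 /km² at default seeds) and is reported, not imposed.
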