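"""Distance and capacity-distance allocation mechanisms."""

import numpy as np
import pandas as pd
import pytest

from capdist.allocation import (
    InfeasibleError,
    allocate_capacity_distance,
    allocate_distance,
    facility_rank,
    gap_table,
    load_summary,
)
from capdist.network import TravelTimeMatrix

from conftest import as_nested_dict, random_instance
from naive_allocator import naive_capacity_distance


class TestAllocateDistance:
    def test_row_minimum(self, toy_matrix):
        res = allocate_distance(toy_matrix)
        assert res.assignment.to_dict() == {"P1": "A", "P2": "A", "P3": "B"}
        assert res.time.to_dict() == {"P1": 1.0, "P2": 2.0, "P3": 2.0}
        assert (res.rank == 1).all()

    def test_single_facility_forced(self):
        mat = TravelTimeMatrix(("P1", "P2"), ("A",), np.array([[40.0], [90.0]]))
        res = allocate_distance(mat)
        assert set(res.assignment) == {"A"}

    def test_tie_goes_to_lower_facility_id(self):
        mat = TravelTimeMatrix(("P",), ("B", "A"), np.array([[3.0, 3.0]]))
        assert allocate_distance(mat).assignment["P"] == "A"


class TestAllocateCapacityDistance:
    def test_worked_rounds(self, toy_matrix, toy_capacities):
        res = allocate_capacity_distance(toy_matrix, toy_capacities)
        t = res.table
        assert t.loc["P1", "facility_id"] == "A"
        assert t.loc["P2", "facility_id"] == "B"
        assert t.loc["P3", "facility_id"] == "B"
        assert t.loc["P1", "time_min"] == 1.0 and t.loc["P1", "rank"] == 1
        assert t.loc["P2", "time_min"] == 4.0 and t.loc["P2", "rank"] == 2
        assert t.loc["P3", "time_min"] == 2.0 and t.loc["P3", "rank"] == 1
        assert list(t["round"]) == [1, 2, 1]
        assert res.n_rounds == 2

    def test_slack_capacity_reduces_to_distance_model(self, toy_matrix):
        cap = allocate_capacity_distance(toy_matrix, {"A": 3, "B": 3})
        dist = allocate_distance(toy_matrix)
        assert cap.assignment.to_dict() == dist.assignment.to_dict()

    def test_single_open_facility(self, toy_matrix):
        res = allocate_capacity_distance(toy_matrix, {"A": 0, "B": 3})
        assert set(res.assignment) == {"B"}
        assert res.table.loc["P1", "rank"] == 2
        assert res.table.loc["P3", "rank"] == 1

    def test_infeasible_raises_by_default(self, toy_matrix):
        with pytest.raises(InfeasibleError, match="2 < 3"):
            allocate_capacity_distance(toy_matrix, {"A": 1, "B": 1})

    def test_partial_mode_flags_unassigned(self, toy_matrix):
        res = allocate_capacity_distance(toy_matrix, {"A": 1, "B": 1},
                                         allow_unassigned=True)
        assert len(res.unassigned) == 1
        assigned = res.table.dropna(subset=["facility_id"])
        assert len(assigned) == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_capacity_never_exceeded_and_complete(self, seed):
        rng = np.random.default_rng(seed)
        matrix, caps = random_instance(rng)
        res = allocate_capacity_distance(matrix, caps)
        counts = res.facility_counts()
        for f, c in caps.items():
            assert counts.get(f, 0) <= c
        assert res.table["facility_id"].notna().all()

    @pytest.mark.parametrize("seed", range(30))
    def test_dominance_over_distance_model(self, seed):
        rng = np.random.default_rng(100 + seed)
        matrix, caps = random_instance(rng)
        cap = allocate_capacity_distance(matrix, caps)
        dist = allocate_distance(matrix)
        assert (cap.time >= dist.time - 1e-12).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        matrix, caps = random_instance(rng)
        res = allocate_capacity_distance(matrix, caps)
        oracle = naive_capacity_distance(as_nested_dict(matrix), caps)
        assert res.assignment.to_dict() == oracle

    def test_deterministic_across_runs(self, toy_matrix, toy_capacities):
        a = allocate_capacity_distance(toy_matrix, toy_capacities)
        b = allocate_capacity_distance(toy_matrix, toy_capacities)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_capacity_entry_raises(self, toy_matrix):
        with pytest.raises(KeyError, match="B"):
            allocate_capacity_distance(toy_matrix, {"A": 5})


class TestFacilityRank:
    def test_nearest_is_rank_one(self, toy_matrix):
        assert facility_rank(toy_matrix, "P1", "A") == 1

    def test_second_nearest(self, toy_matrix):
        assert facility_rank(toy_matrix, "P2", "B") == 2

    def test_equidistant_facilities_share_best_rank(self):
        mat = TravelTimeMatrix(("P",), ("A", "B", "C"), np.array([[2.0, 2.0, 2.0]]))
        assert all(facility_rank(mat, "P", f) == 1 for f in ("A", "B", "C"))


class TestGapTable:
    def test_worked_instance(self, toy_matrix, toy_capacities):
        dist = allocate_distance(toy_matrix)
        cap = allocate_capacity_distance(toy_matrix, toy_capacities)
        gaps = gap_table(dist, cap)
        assert gaps.table.loc[1, "n"] == 2
        assert gaps.table.loc[1, "gap_median"] == 0.0
        assert gaps.table.loc[2, "n"] == 1
        assert gaps.table.loc[2, "gap_median"] == 2.0
        assert gaps.share_non_nearest == pytest.approx(1 / 3)

    def test_identical_results_have_zero_gaps(self, toy_matrix):
        dist = allocate_distance(toy_matrix)
        cap = allocate_capacity_distance(toy_matrix, {"A": 5, "B": 5})
        gaps = gap_table(dist, cap)
        assert (gaps.table["gap_median"] == 0).all()
        assert gaps.share_non_nearest == 0.0

    def test_printed_share_arithmetic(self):
        # headline share of patients not at their nearest facility
        assert round(100 * 2662 / 7374, 1) == 36.1


class TestLoadSummary:
    def test_worked_instance(self, toy_matrix, toy_capacities):
        ls = load_summary(toy_matrix, toy_capacities)
        assert ls.per_facility.loc["A", "demand"] == 2
        assert ls.per_facility.loc["B", "demand"] == 1
        assert ls.per_facility.loc["A", "excess"] == 1
        assert ls.per_facility.loc["B", "slack"] == 1
        assert ls.excess_total == 1 and ls.slack_total == 1

    def test_exact_capacity_gives_zero_excess_and_slack(self, toy_matrix):
        ls = load_summary(toy_matrix, {"A": 2, "B": 1})
        assert ls.excess_total == 0 and ls.slack_total == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_identity(self, seed):
        rng = np.random.default_rng(300 + seed)
        matrix, caps = random_instance(rng, feasible=False)
        ls = load_summary(matrix, caps)
        assert ls.slack_total - ls.excess_total == sum(caps.values()) - len(
            matrix.patient_ids
        )
        assert (ls.per_facility["excess"] * ls.per_facility["slack"] == 0).all()
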