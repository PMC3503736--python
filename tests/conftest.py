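import numpy as np
import pandas as pd
import pytest

from capdist.network import TravelTimeMatrix


@pytest.fixture
def toy_matrix() -> TravelTimeMatrix:
    """Three patients, two facilities; under capacities A:1, B:2 the round
    mechanism sends P1->A, P3->B in round 1 and P2->B in round 2."""
    return TravelTimeMatrix(
        patient_ids=("P1", "P2", "P3"),
        facility_ids=("A", "B"),
        times=np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 2.0]]),
    )


@pytest.fixture
def toy_capacities() -> dict[str, int]:
    return {"A": 1, "B": 2}


def random_instance(rng: np.random.Generator, max_patients=12, max_facilities=5,
                    feasible=True, integer_times=True):
    """Small random allocation instance; integer times make ties common."""
    n_p = int(rng.integers(1, max_patients + 1))
    n_f = int(rng.integers(1, max_facilities + 1))
    if integer_times:
        times = rng.integers(0, 10, size=(n_p, n_f)).astype(float)
    else:
        times = rng.uniform(0, 60, size=(n_p, n_f))
    caps = rng.integers(0, n_p + 2, size=n_f)
    if feasible and caps.sum() < n_p:
        caps[int(rng.integers(0, n_f))] += n_p - caps.sum()
    matrix = TravelTimeMatrix(
        tuple(f"P{i:02d}" for i in range(n_p)),
        tuple(f"F{j}" for j in range(n_f)),
        times,
    )
    return matrix, {f"F{j}": int(caps[j]) for j in range(n_f)}


def as_nested_dict(matrix: TravelTimeMatrix) -> dict[str, dict[str, float]]:
    return {
        p: {f: float(matrix.times[i, j]) for j, f in enumerate(matrix.facility_ids)}
        for i, p in enumerate(matrix.patient_ids)
    }


@pytest.fixture
def non_monotone_instance() -> tuple[TravelTimeMatrix, dict[str, int]]:
    """Constructed counterexample: closing facility F *shortens* patient w's
    commute (10 -> 1 min) by re-timing w's proposal to G from round 2 to
    round 1, where w outcompetes r.  Guards the round mechanism against
    being 'fixed' toward global optimality."""
    matrix = TravelTimeMatrix(
        patient_ids=("q", "r", "w", "z"),
        facility_ids=("E", "F", "G", "H"),
        times=np.array(
            [
                [9.0, 9.0, 2.0, 8.0],    # q
                [9.0, 9.0, 3.0, 7.0],    # r
                [30.0, 0.5, 1.0, 10.0],  # w
                [1.0, 0.4, 5.0, 20.0],   # z
            ]
        ),
    )
    return matrix, {"E": 1, "F": 1, "G": 2, "H": 4}
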