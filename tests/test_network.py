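"""Road-network generation and shortest-path travel-time matrices."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from capdist.network import (
    MatrixFormatError,
    RoadNetwork,
    TravelTimeMatrix,
    generate_network,
    load_matrix,
    save_matrix,
    travel_time_matrix,
)
from capdist.region import PRESETS, Region, generate_region


def build_network(nodes, edges, speed_table):
    """nodes: {id: (x, y)}; edges: [(u, v, length_km, speed_class)]."""
    g = nx.Graph()
    for n, (x, y) in nodes.items():
        g.add_node(n, x_km=x, y_km=y)
    for u, v, length, cls in edges:
        g.add_edge(u, v, length_km=length, speed_class=cls)
    return RoadNetwork(graph=g, speed_table=speed_table)


def points_df(kind, coords):
    col = "patient_id" if kind == "patient" else "facility_id"
    return pd.DataFrame(
        [{col: pid, "x_km": x, "y_km": y} for pid, (x, y) in coords.items()]
    )


def point_region(coords):
    blocks = pd.DataFrame(
        {
            "block_id": ["B0"],
            "x_km": [coords[0]], "y_km": [coords[1]],
            "area_km2": [1.0], "population": [1], "density": [1.0],
        }
    )
    empty_p = pd.DataFrame(columns=["patient_id", "block_id", "x_km", "y_km"])
    empty_f = pd.DataFrame(columns=["facility_id", "x_km", "y_km", "capacity"])
    return Region(blocks, empty_p, empty_f, seed=0)


class TestGenerateNetwork:
    def test_minimal_grid_edge_times(self):
        net = generate_network(
            point_region((0.0, 0.0)), spacing_km=10.0, extra_edge_prob=0.0,
            speed_table={"local": 30.0}, seed=1,
        )
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 4
        for u, v in net.graph.edges:
            assert net.edge_minutes(u, v) == pytest.approx(20.0)

    def test_seeded_determinism(self):
        reg = generate_region(PRESETS["tiny"].replace(seed=3))
        n1 = generate_network(reg, seed=5)
        n2 = generate_network(reg, seed=5)
        e1 = sorted((u, v, d["length_km"], d["speed_class"])
                    for u, v, d in n1.graph.edges(data=True))
        e2 = sorted((u, v, d["length_km"], d["speed_class"])
                    for u, v, d in n2.graph.edges(data=True))
        assert e1 == e2

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_study_scale_network_connected(self, seed):
        reg = generate_region(PRESETS["hiroshima"].replace(seed=seed))
        net = generate_network(reg, seed=seed)
        assert nx.is_connected(net.graph)


class TestTravelTimeMatrix:
    def test_single_edge(self):
        net = build_network(
            {1: (0, 0), 2: (10, 0)}, [(1, 2, 10.0, "major")], {"major": 60.0}
        )
        mat = travel_time_matrix(
            net, points_df("patient", {"P": (0, 0)}), points_df("facility", {"F": (10, 0)})
        )
        assert mat.times[0, 0] == pytest.approx(10.0)

    def test_faster_detour_beats_direct(self):
        # A-B direct 10 km at 40 km/h (15 min) vs A-C-B 12 km at 60 km/h (12 min)
        net = build_network(
            {"A": (0, 0), "B": (10, 0), "C": (5, 3)},
            [("A", "B", 10.0, "slow"), ("A", "C", 6.0, "fast"), ("C", "B", 6.0, "fast")],
            {"slow": 40.0, "fast": 60.0},
        )
        mat = travel_time_matrix(
            net, points_df("patient", {"P": (0, 0)}), points_df("facility", {"F": (10, 0)})
        )
        assert mat.times[0, 0] == pytest.approx(12.0)

    def test_same_node_is_zero(self):
        net = build_network(
            {1: (0, 0), 2: (5, 0)}, [(1, 2, 5.0, "local")], {"local": 30.0}
        )
        mat = travel_time_matrix(
            net, points_df("patient", {"P": (0.1, 0)}), points_df("facility", {"F": (-0.1, 0)})
        )
        assert mat.times[0, 0] == 0.0

    def _random_network(self, rng, n_nodes):
        while True:
            g = nx.gnp_random_graph(n_nodes, 0.5, seed=int(rng.integers(2**31)))
            if nx.is_connected(g) and g.number_of_edges() > 0:
                break
        nodes = {i: (float(i), float(i % 2)) for i in g.nodes}
        classes = ["a", "b", "c"]
        edges = [
            (u, v, float(rng.uniform(1, 20)), classes[int(rng.integers(3))])
            for u, v in g.edges
        ]
        return build_network(nodes, edges, {"a": 30.0, "b": 50.0, "c": 80.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_enumeration(self, seed):
        """On networks of <= 8 nodes, entries equal the brute-force minimum
        over all simple paths."""
        rng = np.random.default_rng(seed)
        net = self._random_network(rng, int(rng.integers(3, 9)))
        nodes, xy = net.node_coords()
        patients = points_df("patient", {f"P{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        facilities = points_df("facility", {f"F{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        mat = travel_time_matrix(net, patients, facilities)
        for i, src in enumerate(nodes):
            for j, dst in enumerate(nodes):
                if src == dst:
                    assert mat.times[i, j] == 0.0
                    continue
                best = min(
                    sum(net.edge_minutes(a, b) for a, b in zip(path, path[1:]))
                    for path in nx.all_simple_paths(net.graph, src, dst)
                )
                assert mat.times[i, j] == pytest.approx(best, abs=1e-9)

    def test_triangle_inequality_between_nodes(self):
        rng = np.random.default_rng(42)
        net = self._random_network(rng, 7)
        nodes, xy = net.node_coords()
        pts = points_df("patient", {f"P{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        fac = points_df("facility", {f"F{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        t = travel_time_matrix(net, pts, fac).times
        for a, b, c in itertools.permutations(range(len(nodes)), 3):
            assert t[a, c] <= t[a, b] + t[b, c] + 1e-9

    def test_doubling_speeds_halves_times(self):
        rng = np.random.default_rng(7)
        net = self._random_network(rng, 6)
        doubled = RoadNetwork(
            graph=net.graph, speed_table={c: 2 * v for c, v in net.speed_table.items()}
        )
        nodes, xy = net.node_coords()
        pts = points_df("patient", {f"P{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        fac = points_df("facility", {f"F{n}": tuple(xy[i]) for i, n in enumerate(nodes)})
        t1 = travel_time_matrix(net, pts, fac).times
        t2 = travel_time_matrix(doubled, pts, fac).times
        np.testing.assert_allclose(t2, t1 / 2.0)


class TestMatrixIO:
    def test_round_trip_exact(self, tmp_path):
        mat = TravelTimeMatrix(("P1",), ("F1",), np.array([[7.09]]))
        path = tmp_path / "m.csv"
        save_matrix(mat, path)
        loaded = load_matrix(path)
        assert loaded.patient_ids == mat.patient_ids
        assert loaded.facility_ids == mat.facility_ids
        np.testing.assert_array_equal(loaded.times, mat.times)

    def test_full_precision_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = TravelTimeMatrix(
            tuple(f"P{i}" for i in range(5)),
            tuple(f"F{j}" for j in range(3)),
            rng.uniform(0, 90, (5, 3)),
        )
        path = tmp_path / "m.csv"
        save_matrix(mat, path)
        np.testing.assert_array_equal(load_matrix(path).times, mat.times)

    def test_negative_entry_names_cell(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,F1,F2\nP1,3.0,-1.5\n")
        with pytest.raises(MatrixFormatError, match=r"'P1'.*'F2'"):
            load_matrix(path)

    def test_non_numeric_entry_names_cell(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,F1\nP1,abc\n")
        with pytest.raises(MatrixFormatError, match=r"'P1'.*'F1'"):
            load_matrix(path)

    def test_ragged_row_is_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,F1,F2\nP1,1.0,2.0\nP2,1.0,2.0,3.0\n")
        with pytest.raises(MatrixFormatError):
            load_matrix(path)

    def test_missing_entry_is_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,F1,F2\nP1,1.0,\n")
        with pytest.raises(MatrixFormatError, match=r"'P1'.*'F2'"):
            load_matrix(path)
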