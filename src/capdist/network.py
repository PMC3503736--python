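"""Synthetic road networks and patient-by-facility travel-time matrices.

Travel times are driving minutes over a network of speed-classed road
segments: an edge of length L km in a class driven at v km/h costs
60*L/v minutes.  Patients and facilities snap to their nearest network node
(planar Euclidean distance) and each matrix entry is the shortest-path time
between the two snapped nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "DEFAULT_SPEED_TABLE",
    "RoadNetwork",
    "NetworkGenerationError",
    "MatrixFormatError",
    "TravelTimeMatrix",
    "generate_network",
    "travel_time_matrix",
    "save_matrix",
    "load_matrix",
    "write_network_geojson",
]

#: default speed classes, km/h; configurable to any number of classes
DEFAULT_SPEED_TABLE: dict[str, float] = {
    "highway": 80.0,
    "major": 60.0,
    "arterial": 50.0,
    "collector": 40.0,
    "local": 30.0,
}

_CLASS_WEIGHTS = {
    "highway": 0.05,
    "major": 0.10,
    "arterial": 0.20,
    "collector": 0.25,
    "local": 0.40,
}


class NetworkGenerationError(RuntimeError):
    """The generator could not produce a connected network."""


class MatrixFormatError(ValueError):
    """A travel-time matrix file violates the expected CSV format."""


@dataclass
class RoadNetwork:
    """Undirected road network with per-edge length and speed class."""

    graph: nx.Graph
    speed_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEED_TABLE)
    )

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if data["length_km"] <= 0:
                raise ValueError(f"edge ({u},{v}) has non-positive length")
            cls = data["speed_class"]
            if cls not in self.speed_table or self.speed_table[cls] <= 0:
                raise ValueError(f"edge ({u},{v}) has unknown speed class {cls!r}")

    def edge_minutes(self, u, v) -> float:
        data = self.graph.edges[u, v]
        return 60.0 * data["length_km"] / self.speed_table[data["speed_class"]]

    def node_coords(self) -> tuple[list, np.ndarray]:
        nodes = list(self.graph.nodes)
        xy = np.array([[self.graph.nodes[n]["x_km"], self.graph.nodes[n]["y_km"]]
                       for n in nodes])
        return nodes, xy


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Patient-by-facility driving times in minutes."""

    patient_ids: tuple[str, ...]
    facility_ids: tuple[str, ...]
    times: np.ndarray  # shape (n_patients, n_facilities), minutes

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.shape != (len(self.patient_ids), len(self.facility_ids)):
            raise MatrixFormatError("times shape does not match id lists")
        if not np.isfinite(t).all():
            raise MatrixFormatError("travel times must be finite")
        if (t < 0).any():
            raise MatrixFormatError("travel times must be non-negative")
        object.__setattr__(self, "times", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.times.shape

    def row(self, patient_id: str) -> np.ndarray:
        return self.times[self.patient_ids.index(patient_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.times, index=list(self.patient_ids), columns=list(self.facility_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TravelTimeMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))


def _grid_graph(xmin, ymin, nx_, ny_, spacing, rng, extra_edge_prob,
                speed_classes, class_p, drop_prob):
    g = nx.Graph()
    for i in range(nx_):
        for j in range(ny_):
            g.add_node((i, j), x_km=xmin + i * spacing, y_km=ymin + j * spacing)
    mid_i, mid_j = nx_ // 2, ny_ // 2

    def add_edge(a, b, length):
        # central cross-axes are high-speed corridors; the rest is drawn
        # from the class mix
        if (a[0] == b[0] == mid_i) or (a[1] == b[1] == mid_j):
            cls = "highway" if "highway" in class_p else speed_classes[0]
        else:
            cls = rng.choice(speed_classes, p=class_p)
        g.add_edge(a, b, length_km=length, speed_class=str(cls))

    for i in range(nx_):
        for j in range(ny_):
            if i + 1 < nx_ and rng.uniform() >= drop_prob:
                add_edge((i, j), (i + 1, j), spacing)
            if j + 1 < ny_ and rng.uniform() >= drop_prob:
                add_edge((i, j), (i, j + 1), spacing)
            if i + 1 < nx_ and j + 1 < ny_ and rng.uniform() < extra_edge_prob:
                add_edge((i, j), (i + 1, j + 1), spacing * np.sqrt(2.0))
    return g


def generate_network(
    region,
    spacing_km: float = 2.0,
    extra_edge_prob: float = 0.05,
    speed_table: Mapping[str, float] | None = None,
    seed: int = 0,
    edge_drop_prob: float = 0.0,
    max_retries: int = 3,
) -> RoadNetwork:
    """Generate a connected grid-with-shortcuts road network over a region.

    The grid spans the bounding box of all block, patient and facility
    coordinates, padded by one spacing.  Edges take a speed class from
    ``speed_table`` (central cross-axes become high-speed corridors); with
    probability ``extra_edge_prob`` a diagonal shortcut is added.  If random
    edge dropout disconnects the graph the generator retries with halved
    dropout before raising :class:`NetworkGenerationError`.
    """
    speed_table = dict(speed_table or DEFAULT_SPEED_TABLE)
    classes = [c for c in speed_table]
    weights = np.array([_CLASS_WEIGHTS.get(c, 1.0) for c in classes], dtype=float)
    weights /= weights.sum()

    coords = np.concatenate(
        [
            region.blocks[["x_km", "y_km"]].to_numpy(dtype=float),
            region.patients[["x_km", "y_km"]].to_numpy(dtype=float)
            if len(region.patients)
            else np.empty((0, 2)),
            region.facilities[["x_km", "y_km"]].to_numpy(dtype=float)
            if len(region.facilities)
            else np.empty((0, 2)),
        ]
    )
    if len(coords) == 0:
        raise NetworkGenerationError("region has no coordinates to span")
    xmin, ymin = coords.min(axis=0) - spacing_km / 2.0
    xmax, ymax = coords.max(axis=0) + spacing_km / 2.0
    nx_ = max(2, int(np.ceil((xmax - xmin) / spacing_km)) + 1)
    ny_ = max(2, int(np.ceil((ymax - ymin) / spacing_km)) + 1)

    rng = np.random.default_rng(seed)
    drop = edge_drop_prob
    for _ in range(max_retries + 1):
        g = _grid_graph(xmin, ymin, nx_, ny_, spacing_km, rng, extra_edge_prob,
                        classes, weights, drop)
        if nx.is_connected(g):
            return RoadNetwork(graph=g, speed_table=speed_table)
        drop /= 2.0  # densify and retry
    raise NetworkGenerationError(
        "could not generate a connected network; lower edge_drop_prob"
    )


def _snap(xy_points: np.ndarray, node_xy: np.ndarray) -> np.ndarray:
    tree = cKDTree(node_xy)
    _, idx = tree.query(xy_points)
    return np.atleast_1d(idx)


def travel_time_matrix(network: RoadNetwork, patients: pd.DataFrame,
                       facilities: pd.DataFrame) -> TravelTimeMatrix:
    """Shortest-path driving minutes from every patient to every facility.

    Each endpoint snaps to its nearest network node; entries are 0 when both
    snap to the same node.  Requires a connected network and at least one
    facility.
    """
    if len(facilities) == 0:
        raise ValueError("at least one facility is required")
    if len(patients) == 0:
        raise ValueError("at least one patient is required")
    nodes, node_xy = network.node_coords()
    index = {n: i for i, n in enumerate(nodes)}

    rows, cols, minutes = [], [], []
    for u, v, data in network.graph.edges(data=True):
        t = 60.0 * data["length_km"] / network.speed_table[data["speed_class"]]
        rows.append(index[u]); cols.append(index[v]); minutes.append(t)
    n = len(nodes)
    adj = coo_matrix((minutes, (rows, cols)), shape=(n, n)).tocsr()

    p_nodes = _snap(patients[["x_km", "y_km"]].to_numpy(dtype=float), node_xy)
    f_nodes = _snap(facilities[["x_km", "y_km"]].to_numpy(dtype=float), node_xy)

    dist = dijkstra(adj, directed=False, indices=np.unique(f_nodes))
    lookup = {fn: k for k, fn in enumerate(np.unique(f_nodes))}
    times = np.empty((len(p_nodes), len(f_nodes)))
    for j, fn in enumerate(f_nodes):
        times[:, j] = dist[lookup[fn], p_nodes]
    if not np.isfinite(times).all():
        raise NetworkGenerationError("some patient-facility pairs are unreachable")
    return TravelTimeMatrix(
        tuple(map(str, patients["patient_id"])),
        tuple(map(str, facilities["facility_id"])),
        times,
    )


def save_matrix(matrix: TravelTimeMatrix, path) -> None:
    """Write the matrix as CSV: header of facility ids, first column
    patient_id, full-precision minutes (round-trips exactly)."""
    matrix.to_frame().to_csv(path, index_label="patient_id")


def load_matrix(path) -> TravelTimeMatrix:
    """Load a travel-time matrix CSV written by :func:`save_matrix`.

    Raises :class:`MatrixFormatError` naming the offending row and column
    for missing, negative or non-numeric entries, and for ragged rows.
    """
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"malformed matrix CSV: {exc}") from exc
    if df.index.name != "patient_id":
        raise MatrixFormatError("first column must be headed 'patient_id'")
    values = np.empty(df.shape)
    for i, pid in enumerate(df.index):
        for j, fid in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"non-numeric entry at patient {pid!r}, facility {fid!r}: {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise MatrixFormatError(
                    f"non-finite entry at patient {pid!r}, facility {fid!r}"
                )
            if v < 0:
                raise MatrixFormatError(
                    f"negative entry at patient {pid!r}, facility {fid!r}: {v}"
                )
            values[i, j] = v
    return TravelTimeMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                            values)


def write_network_geojson(network: RoadNetwork, path) -> None:
    """Write edges as GeoJSON LineStrings with length_km and speed_class."""
    import json

    features = []
    for u, v, data in network.graph.edges(data=True):
        nu, nv = network.graph.nodes[u], network.graph.nodes[v]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [nu["x_km"], nu["y_km"]],
                        [nv["x_km"], nv["y_km"]],
                    ],
                },
                "properties": {
                    "length_km": data["length_km"],
                    "speed_class": data["speed_class"],
                },
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")
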