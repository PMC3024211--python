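"""Road network distances.

The network is a weighted undirected graph (edge weights = segment length
in miles).  Arbitrary points are connected to the network by snapping to
the nearest node and adding the straight-line access leg, so a
point-to-point query is

    access(a) + shortest_path(snap(a), snap(b)) + access(b)

which keeps distances symmetric and metric.  Identical points are at
distance zero by definition.  Unreachable pairs return ``math.inf`` — the
estimator decides what an unreachable draw means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point

from .geo_model import Facility


@dataclass(frozen=True)
class SnapResult:
    node_id: str
    access_distance: float


class RoadNetwork:
    """Validated undirected road graph with vectorized nearest-node snapping."""

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty road network")
        self.graph = graph
        # node ids sorted ascending: argmin then returns the lowest id on ties
        self._node_ids = sorted(graph.nodes)
        self._coords = np.array(
            [[graph.nodes[n]["x"], graph.nodes[n]["y"]] for n in self._node_ids]
        )

    def node_point(self, node_id: str) -> Point:
        d = self.graph.nodes[node_id]
        return Point(d["x"], d["y"])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RoadNetwork({self.graph.number_of_nodes()} nodes, "
                f"{self.graph.number_of_edges()} edges)")


def build_network(node_table: pd.DataFrame, edge_table: pd.DataFrame) -> RoadNetwork:
    """Build a validated network from node and edge tables.

    Columns: nodes ``node_id,x,y``; edges ``node_a,node_b,length_miles``.
    Parallel edges collapse to the minimum length; self-loops, dangling
    endpoints and non-positive lengths are errors.
    """
    if len(node_table) == 0 or len(edge_table) == 0:
        raise ValueError("node and edge tables must be non-empty")
    g = nx.Graph()
    for _, r in node_table.iterrows():
        nid = str(r["node_id"])
        if nid in g:
            raise ValueError(f"duplicate node_id {nid}")
        g.add_node(nid, x=float(r["x"]), y=float(r["y"]))
    for _, r in edge_table.iterrows():
        a, b = str(r["node_a"]), str(r["node_b"])
        length = float(r["length_miles"])
        if a == b:
            raise ValueError(f"self-loop edge at node {a}")
        for end in (a, b):
            if end not in g:
                raise ValueError(f"edge endpoint {end} is not a node")
        if not (length > 0):
            raise ValueError(f"non-positive edge length {length} on ({a}, {b})")
        if g.has_edge(a, b):
            length = min(length, g.edges[a, b]["length"])
        g.add_edge(a, b, length=length)
    return RoadNetwork(g)


def load_network(nodes_path, edges_path) -> RoadNetwork:
    nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
    edges = pd.read_csv(edges_path, dtype={"node_a": str, "node_b": str})
    return build_network(nodes, edges)


def write_network_csv(network: RoadNetwork, nodes_path, edges_path) -> None:
    g = network.graph
    pd.DataFrame(
        [{"node_id": n, "x": g.nodes[n]["x"], "y": g.nodes[n]["y"]}
         for n in sorted(g.nodes)]
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [{"node_a": a, "node_b": b, "length_miles": d["length"]}
         for a, b, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))]
    ).to_csv(edges_path, index=False)


def snap(point: Point, network: RoadNetwork) -> SnapResult:
    """Nearest node by Euclidean distance; ties go to the lowest node_id."""
    d2 = ((network._coords[:, 0] - point.x) ** 2
          + (network._coords[:, 1] - point.y) ** 2)
    i = int(np.argmin(d2))
    return SnapResult(node_id=network._node_ids[i],
                      access_distance=float(math.sqrt(d2[i])))


def network_distance(network: RoadNetwork, point_a: Point, point_b: Point) -> float:
    """Shortest road distance between two points, access legs included."""
    if (point_a.x, point_a.y) == (point_b.x, point_b.y):
        return 0.0
    sa = snap(point_a, network)
    sb = snap(point_b, network)
    if sa.node_id == sb.node_id:
        return sa.access_distance + sb.access_distance
    try:
        path = nx.dijkstra_path_length(network.graph, sa.node_id, sb.node_id,
                                       weight="length")
    except nx.NetworkXNoPath:
        return math.inf
    return sa.access_distance + path + sb.access_distance


def nearest_facility(network: RoadNetwork, point: Point,
                     facilities: Sequence[Facility]) -> tuple[str, float]:
    """Closest facility by network distance; ties go to the lowest facility_id.

    Raises if every facility is unreachable.
    """
    if not facilities:
        raise ValueError("no facilities supplied")
    best: tuple[float, str] | None = None
    for fac in sorted(facilities, key=lambda f: f.facility_id):
        if fac.location is None:
            raise ValueError(f"facility {fac.facility_id} has unresolved location")
        d = network_distance(network, point, fac.location)
        if best is None or d < best[0]:
            best = (d, fac.facility_id)
    if math.isinf(best[0]):
        raise ValueError("all facilities unreachable from query point")
    return best[1], best[0]


class NearestFacilityIndex:
    """Precomputed nearest-facility queries for repeated lookups.

    One single-source Dijkstra per facility; a query is then an O(#facilities)
    table lookup.  Results are identical to :func:`nearest_facility`.
    """

    def __init__(self, network: RoadNetwork, facilities: Iterable[Facility]):
        self.network = network
        self.facilities = sorted(facilities, key=lambda f: f.facility_id)
        if not self.facilities:
            raise ValueError("no facilities supplied")
        self._snaps: list[SnapResult] = []
        self._dist_maps: list[dict[str, float]] = []
        for fac in self.facilities:
            if fac.location is None:
                raise ValueError(f"facility {fac.facility_id} has unresolved location")
            s = snap(fac.location, network)
            self._snaps.append(s)
            self._dist_maps.append(
                nx.single_source_dijkstra_path_length(network.graph, s.node_id,
                                                      weight="length"))

    def query(self, point: Point) -> tuple[str, float]:
        sp = snap(point, self.network)
        best: tuple[float, str] | None = None
        for fac, fsnap, dmap in zip(self.facilities, self._snaps, self._dist_maps):
            if (point.x, point.y) == (fac.location.x, fac.location.y):
                d = 0.0
            elif sp.node_id == fsnap.node_id:
                d = sp.access_distance + fsnap.access_distance
            else:
                path = dmap.get(sp.node_id)
                d = math.inf if path is None else (
                    sp.access_distance + path + fsnap.access_distance)
            if best is None or d < best[0]:
                best = (d, fac.facility_id)
        if math.isinf(best[0]):
            raise ValueError("all facilities unreachable from query point")
        return best[1], best[0]
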