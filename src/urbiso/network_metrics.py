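"""Degree-based isolation classes and gravity-flow centrality on road networks.

The centrality of a city is the total gravity-model flow routed through it
along fastest paths over all unordered city pairs — a flow-weighted
betweenness.  Border-crossing edges are penalised by a fixed extra travel
time before routing.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import UrbanNetwork
from .errors import AnalysisError, ValidationError

ISOLATION_CLASSES = ("high", "medium", "low")
CENTRALITY_CLASSES = ("Q1_lowest", "Q2", "Q3", "Q4_highest")


@dataclass(frozen=True)
class GravityParams:
    """Gravity-model parameters: distance-decay exponent and border penalty."""

    gamma: float = 2.8
    border_penalty_h: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if self.border_penalty_h < 0:
            raise ValidationError("border_penalty_h must be >= 0")


def compute_degree(network: UrbanNetwork) -> dict[str, int]:
    """Number of incident road edges per city (parallel edges count separately).

    Edges terminating at junctions count toward the city's degree like any
    other incident edge: the degree counts highways leaving the city, not
    distinct neighbouring cities.
    """
    counts: dict[str, int] = {}
    for col in ("from_node", "to_node"):
        for nid, n in network.edges[col].value_counts().items():
            counts[nid] = counts.get(nid, 0) + int(n)
    city_nodes = network.city_nodes()
    return {
        row.city_ref: counts.get(row.node_id, 0)
        for row in city_nodes.itertuples()
    }


def classify_isolation(degree: int) -> str:
    """Map a city degree to its isolation class: high D<=2, medium 3-5, low >=6."""
    if degree < 0:
        raise ValidationError(f"degree must be >= 0, got {degree}")
    if degree <= 2:
        return "high"
    if degree <= 5:
        return "medium"
    return "low"


def gravity_flow(pop_o: float, pop_d: float, travel_time: float,
                 params: GravityParams = GravityParams()) -> float:
    """Gravity-model flow P_o * P_d / t^gamma between an origin and destination."""
    if travel_time <= 0:
        raise ValidationError(f"travel_time must be > 0, got {travel_time}")
    return pop_o * pop_d / travel_time ** params.gamma


def _adjacency(network: UrbanNetwork, params: GravityParams) -> dict[str, list[tuple[str, float]]]:
    """Adjacency with effective weights; parallel edges collapse to the fastest."""
    best: dict[tuple[str, str], float] = {}
    for row in network.edges.itertuples():
        w = row.travel_time_h + (params.border_penalty_h if row.crosses_border else 0.0)
        for a, b in ((row.from_node, row.to_node), (row.to_node, row.from_node)):
            key = (a, b)
            if key not in best or w < best[key]:
                best[key] = w
    adj: dict[str, list[tuple[str, float]]] = {nid: [] for nid in network.nodes["node_id"]}
    for (a, b), w in best.items():
        adj[a].append((b, w))
    for nbrs in adj.values():
        nbrs.sort()
    return adj


def _sssp_lex(adj: dict[str, list[tuple[str, float]]],
              source: str) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Dijkstra returning, per reachable node, the fastest route from source.

    Among equal-time routes the lexicographically smallest node sequence is
    chosen; the heap orders entries by (time, path) so label-setting pops
    exactly that route first (the lexicographic order is extension-monotone
    because labelled paths are simple).
    """
    settled: dict[str, tuple[float, tuple[str, ...]]] = {}
    dist: dict[str, float] = {source: 0.0}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        d, path = heapq.heappop(heap)
        u = path[-1]
        if u in settled:
            continue
        settled[u] = (d, path)
        for v, w in adj[u]:
            if v in settled:
                continue
            nd = d + w
            if v not in dist or nd <= dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, path + (v,)))
    return settled


def fastest_paths(network: UrbanNetwork, params: GravityParams = GravityParams(),
                  sources: list[str] | None = None,
                  ) -> dict[str, dict[str, tuple[float, tuple[str, ...]]]]:
    """All-pairs fastest routes between city nodes by penalised travel time.

    Returns ``{origin_node: {dest_node: (total_time_h, node_path)}}`` for city
    nodes only.  Unreachable destinations are absent from the inner mapping.
    """
    city_ids = list(network.city_nodes()["node_id"])
    adj = _adjacency(network, params)
    out = {}
    for src in sources if sources is not None else city_ids:
        settled = _sssp_lex(adj, src)
        out[src] = {c: settled[c] for c in city_ids if c != src and c in settled}
    return out


def compute_centrality(network: UrbanNetwork, cities: pd.DataFrame,
                       params: GravityParams = GravityParams(),
                       include_endpoints: bool = False) -> dict[str, float]:
    """Total gravity flow routed through each city over all unordered city pairs.

    For every unordered pair of cities {o, d} the flow P_o P_d / N_od^gamma is
    accumulated onto every *intermediate* city of the fastest o->d route
    (junction nodes accumulate nothing).  ``include_endpoints=True`` switches
    to the convention where o and d themselves also receive the flow.
    Unreachable pairs contribute nothing.
    """
    city_nodes = network.city_nodes()
    node_of = dict(zip(city_nodes["city_ref"], city_nodes["node_id"]))
    missing = set(cities["city_id"]) - set(node_of)
    if missing:
        raise AnalysisError(f"cities missing from network: {sorted(missing)[:5]}")
    pop = dict(zip(cities["city_id"], cities["population"].astype(float)))
    city_of_node = {v: k for k, v in node_of.items()}

    centrality = {cid: 0.0 for cid in cities["city_id"]}
    adj = _adjacency(network, params)
    ordered = sorted(cities["city_id"])
    for i, o in enumerate(ordered):
        settled = _sssp_lex(adj, node_of[o])
        for d in ordered[i + 1:]:
            hit = settled.get(node_of[d])
            if hit is None:
                continue
            n_od, path = hit
            flow = pop[o] * pop[d] / n_od ** params.gamma
            members = path if include_endpoints else path[1:-1]
            for node in members:
                cid = city_of_node.get(node)
                if cid is not None:
                    centrality[cid] += flow
    return centrality


def classify_centrality_quartiles(centrality: dict[str, float]) -> dict[str, str]:
    """Partition cities into centrality quartiles by city count.

    Cities are ranked by (centrality, city_id) — the id breaks ties for a
    deterministic partition — and split at the 25/50/75 rank cut points
    ``floor(n*k/4)``, giving sizes as equal as possible.
    """
    n = len(centrality)
    if n < 4:
        raise AnalysisError(f"need >= 4 cities for quartiles, got {n}")
    ranked = sorted(centrality, key=lambda cid: (centrality[cid], cid))
    cuts = [n * k // 4 for k in range(5)]
    out: dict[str, str] = {}
    for k, label in enumerate(CENTRALITY_CLASSES):
        for cid in ranked[cuts[k]:cuts[k + 1]]:
            out[cid] = label
    return out


def compute_metrics(network: UrbanNetwork, cities: pd.DataFrame,
                    params: GravityParams = GravityParams(),
                    with_centrality: bool = True) -> pd.DataFrame:
    """Per-city metrics table: degree, isolation class, centrality, quartile."""
    degree = compute_degree(network)
    missing = set(cities["city_id"]) - set(degree)
    if missing:
        raise AnalysisError(f"cities missing from network: {sorted(missing)[:5]}")
    df = pd.DataFrame({"city_id": cities["city_id"].astype(str)})
    df["degree"] = df["city_id"].map(degree).astype(int)
    df["isolation_class"] = df["degree"].map(classify_isolation)
    if with_centrality:
        cent = compute_centrality(network, cities, params)
        df["centrality"] = df["city_id"].map(cent)
        quart = classify_centrality_quartiles(cent)
        df["centrality_class"] = df["city_id"].map(quart)
    else:
        df["centrality"] = np.nan
        df["centrality_class"] = ""
    return df
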