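import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from urbiso import network_metrics as nm
from urbiso.errors import AnalysisError, ValidationError

from conftest import make_cities, make_network


# --- degree & isolation ---

def test_path_graph_degrees(path_graph):
    cities, network = path_graph
    assert nm.compute_degree(network) == {"A": 1, "B": 2, "C": 1}


def test_isolated_city_degree_zero():
    cities = make_cities([("A", 0, 0, "X", 1), ("B", 1, 0, "X", 1), ("C", 2, 0, "X", 1)])
    net = make_network(cities, [("A", "B", 1.0)])
    assert nm.compute_degree(net)["C"] == 0


def test_star_hub_degree():
    rows = [("H", 0.0, 0.0, "X", 1)] + [(f"S{i}", float(i + 1), 0.0, "X", 1)
                                        for i in range(6)]
    cities = make_cities(rows)
    net = make_network(cities, [("H", f"S{i}", 1.0) for i in range(6)])
    assert nm.compute_degree(net)["H"] == 6


def test_parallel_edges_count_separately():
    cities = make_cities([("A", 0, 0, "X", 1), ("B", 1, 0, "X", 1)])
    net = make_network(cities, [("A", "B", 1.0), ("A", "B", 2.0)])
    assert nm.compute_degree(net) == {"A": 2, "B": 2}


def test_junction_terminated_edges_count():
    cities = make_cities([("A", 0, 0, "X", 1)])
    net = make_network(cities, [("A", "j1", 1.0)],
                       junctions=[("j1", 0.5, 0.0, "X")])
    assert nm.compute_degree(net)["A"] == 1


def test_degree_sum_is_twice_edges(planted_500):
    _, cities, network, _, _, _ = planted_500
    deg = nm.compute_degree(network)
    assert sum(deg.values()) == 2 * network.n_edges  # all nodes are cities here


@pytest.mark.parametrize("degree,expected", [
    (0, "high"), (1, "high"), (2, "high"),
    (3, "medium"), (4, "medium"), (5, "medium"),
    (6, "low"), (7, "low"), (40, "low"),
])
def test_classify_isolation_thresholds(degree, expected):
    assert nm.classify_isolation(degree) == expected


def test_classify_isolation_negative():
    with pytest.raises(ValidationError):
        nm.classify_isolation(-1)


@given(st.integers(min_value=0, max_value=10 ** 6))
def test_classify_isolation_total_and_monotone(degree):
    cls = nm.classify_isolation(degree)
    assert cls in nm.ISOLATION_CLASSES
    order = {"high": 0, "medium": 1, "low": 2}
    assert order[nm.classify_isolation(degree + 1)] >= order[cls]


# --- gravity flow ---

def test_gravity_flow_identity():
    assert nm.gravity_flow(1, 1, 1.0) == 1.0


def test_gravity_flow_value():
    assert nm.gravity_flow(100, 200, 10.0) == pytest.approx(31.6978, abs=1e-4)


def test_gravity_flow_halves_per_doubling():
    params = nm.GravityParams(gamma=2.8)
    f1 = nm.gravity_flow(50, 70, 3.0, params)
    f2 = nm.gravity_flow(50, 70, 6.0, params)
    assert f1 / f2 == pytest.approx(2 ** 2.8, rel=1e-12)


def test_gravity_flow_bad_time():
    with pytest.raises(ValidationError):
        nm.gravity_flow(1, 1, 0.0)


def test_gravity_params_validation():
    with pytest.raises(ValidationError):
        nm.GravityParams(gamma=-0.1)
    with pytest.raises(ValidationError):
        nm.GravityParams(border_penalty_h=-1.0)


# --- fastest paths ---

def test_fastest_paths_path_graph(path_graph):
    cities, network = path_graph
    paths = nm.fastest_paths(network, nm.GravityParams(border_penalty_h=0.0))
    time_ac, route_ac = paths["A"]["C"]
    assert time_ac == 2.0
    assert route_ac == ("A", "B", "C")


def test_border_penalty_added(path_graph):
    cities, network = path_graph
    # fixture B-C edge crosses no border; rebuild with a border on B-C
    cities2 = make_cities([("A", 0, 0, "X", 1), ("B", 0.5, 0, "X", 1),
                           ("C", 1.0, 0, "Y", 1)])
    net = make_network(cities2, [("A", "B", 1.0), ("B", "C", 1.0)])
    assert net.edges["crosses_border"].tolist() == [False, True]
    paths = nm.fastest_paths(net, nm.GravityParams(border_penalty_h=2.0))
    assert paths["B"]["C"][0] == 3.0  # 1 h edge + 2 h penalty
    assert paths["A"]["C"][0] == 4.0


def test_tie_broken_lexicographically():
    # A->D via B or via C, both cost 2; path through B is lexicographically smaller
    cities = make_cities([("A", 0, 0, "X", 1), ("B", 1, 1, "X", 1),
                          ("C", 1, -1, "X", 1), ("D", 2, 0, "X", 1)])
    net = make_network(cities, [("A", "B", 1.0), ("B", "D", 1.0),
                                ("A", "C", 1.0), ("C", "D", 1.0)])
    for _ in range(3):  # identical across runs
        paths = nm.fastest_paths(net)
        assert paths["A"]["D"][1] == ("A", "B", "D")


def test_unreachable_pair_excluded():
    cities = make_cities([("A", 0, 0, "X", 1), ("B", 1, 0, "X", 1),
                          ("C", 5, 5, "X", 1)])
    net = make_network(cities, [("A", "B", 1.0)])
    paths = nm.fastest_paths(net)
    assert "C" not in paths["A"]
    cent = nm.compute_centrality(net, cities)
    assert cent == {"A": 0.0, "B": 0.0, "C": 0.0}


# --- centrality ---

def test_path_graph_centrality(path_graph):
    cities, network = path_graph
    cent = nm.compute_centrality(network, cities,
                                 nm.GravityParams(border_penalty_h=0.0))
    assert cent["B"] == pytest.approx(2 ** -2.8, rel=1e-12)
    assert cent["B"] == pytest.approx(0.143587, abs=1e-6)
    assert cent["A"] == 0.0 and cent["C"] == 0.0


def test_include_endpoints_switch(path_graph):
    cities, network = path_graph
    params = nm.GravityParams(border_penalty_h=0.0)
    cent = nm.compute_centrality(network, cities, params, include_endpoints=True)
    # B gains its own endpoint flows: A-B (1h) and B-C (1h) and stays on A-C
    assert cent["B"] == pytest.approx(1.0 + 1.0 + 2 ** -2.8, rel=1e-12)
    assert cent["A"] == pytest.approx(1.0 + 2 ** -2.8, rel=1e-12)


def test_leaf_city_centrality_zero(planted_500):
    _, cities, network, _, _, metrics = planted_500
    deg = nm.compute_degree(network)
    leaves = [c for c, d in deg.items() if d == 1]
    cent = dict(zip(metrics["city_id"], metrics["centrality"]))
    assert leaves, "fixture should contain leaf cities"
    assert all(cent[c] == 0.0 for c in leaves)


def test_junctions_accumulate_nothing():
    # A - j - B: junction on the route gets no centrality entry, A/B stay 0
    cities = make_cities([("A", 0, 0, "X", 2), ("B", 1, 0, "X", 3)])
    net = make_network(cities, [("A", "j1", 1.0), ("j1", "B", 1.0)],
                       junctions=[("j1", 0.5, 0.0, "X")])
    cent = nm.compute_centrality(net, cities)
    assert set(cent) == {"A", "B"}
    assert cent == {"A": 0.0, "B": 0.0}


def test_population_scale_property(rng):
    cities, net = _random_instance(rng, n_nodes=15, n_cities=8)
    c1 = nm.compute_centrality(net, cities)
    cities2 = cities.assign(population=cities["population"] * 7)
    c2 = nm.compute_centrality(net, cities2)
    for cid in c1:
        assert c2[cid] == pytest.approx(49 * c1[cid], rel=1e-9, abs=1e-30)


def test_added_shortcut_increases_throughflow():
    # long way round D (10 h) vs adding a fast route through B
    cities = make_cities([("A", 0, 0, "X", 10), ("B", 1, 0, "X", 1),
                          ("C", 2, 0, "X", 10), ("D", 1, 2, "X", 1)])
    slow = make_network(cities, [("A", "D", 5.0), ("D", "C", 5.0)])
    base = nm.compute_centrality(slow, cities)["B"]
    fast = make_network(cities, [("A", "D", 5.0), ("D", "C", 5.0),
                                 ("A", "B", 1.0), ("B", "C", 1.0)])
    faster = nm.compute_centrality(fast, cities)["B"]
    assert base == 0.0
    assert faster > base


# --- brute-force oracle ---

def _random_instance(rng, n_nodes, n_cities, extra_edges=3):
    """Random connected network: labelled tree + a few extra edges."""
    tree = nx.random_labeled_tree(n_nodes, seed=int(rng.integers(2 ** 31)))
    g = nx.Graph(tree)
    nodes = list(g.nodes)
    for _ in range(extra_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        if not g.has_edge(nodes[u], nodes[v]):
            g.add_edge(nodes[u], nodes[v])
    ids = [f"n{k:02d}" for k in range(n_nodes)]
    city_idx = sorted(rng.choice(n_nodes, size=n_cities, replace=False))
    city_rows, junctions, name = [], [], {}
    for k in range(n_nodes):
        lon, lat = float(rng.uniform(0, 5)), float(rng.uniform(0, 5))
        country = "X" if rng.random() < 0.8 else "Y"
        if k in city_idx:
            city_rows.append((ids[k], lon, lat, country, int(rng.integers(1, 10 ** 5))))
        else:
            junctions.append((ids[k], lon, lat, country))
    cities = make_cities(city_rows)
    # integer weights make equal-cost ties common, exercising the tie rule
    edge_rows = [(ids[u], ids[v], float(rng.integers(1, 5)))
                 for u, v in g.edges]
    return cities, make_network(cities, edge_rows, junctions=junctions)


def _oracle_centrality(network, cities, params):
    """Independent recomputation: enumerate every simple path per city pair."""
    g = nx.Graph()
    for row in network.nodes.itertuples():
        g.add_node(row.node_id)
    weights = {}
    for row in network.edges.itertuples():
        w = row.travel_time_h + (params.border_penalty_h if row.crosses_border else 0)
        key = frozenset((row.from_node, row.to_node))
        weights[key] = min(w, weights.get(key, np.inf))
    for key, w in weights.items():
        a, b = sorted(key)
        g.add_edge(a, b, weight=w)
    node_of = dict(zip(network.city_nodes()["city_ref"],
                       network.city_nodes()["node_id"]))
    city_of = {v: k for k, v in node_of.items()}
    pop = dict(zip(cities["city_id"], cities["population"].astype(float)))
    cent = {cid: 0.0 for cid in cities["city_id"]}
    for o, d in itertools.combinations(sorted(cities["city_id"]), 2):
        best = None
        for path in nx.all_simple_paths(g, node_of[o], node_of[d]):
            cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            cand = (cost, tuple(path))
            if best is None or cand < best:
                best = cand
        if best is None:
            continue
        cost, path = best
        flow = pop[o] * pop[d] / cost ** params.gamma
        for node in path[1:-1]:
            if node in city_of:
                cent[city_of[node]] += flow
    return cent


@pytest.mark.parametrize("seed", range(12))
def test_centrality_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n_nodes = int(rng.integers(6, 18))
    n_cities = int(rng.integers(3, min(9, n_nodes) + 1))
    cities, net = _random_instance(rng, n_nodes, n_cities)
    params = nm.GravityParams()
    got = nm.compute_centrality(net, cities, params)
    want = _oracle_centrality(net, cities, params)
    for cid in want:
        assert got[cid] == pytest.approx(want[cid], rel=1e-9, abs=1e-12)


# --- quartiles ---

def test_quartiles_distinct_eight():
    cent = {f"c{i}": float(i) for i in range(8)}
    classes = nm.classify_centrality_quartiles(cent)
    assert [classes[f"c{i}"] for i in range(8)] == [
        "Q1_lowest", "Q1_lowest", "Q2", "Q2", "Q3", "Q3",
        "Q4_highest", "Q4_highest"]


def test_quartiles_all_ties_deterministic():
    cent = {f"c{i}": 1.0 for i in range(8)}
    classes = nm.classify_centrality_quartiles(cent)
    sizes = {q: sum(v == q for v in classes.values()) for q in set(classes.values())}
    assert sizes == {"Q1_lowest": 2, "Q2": 2, "Q3": 2, "Q4_highest": 2}
    assert classes == nm.classify_centrality_quartiles(cent)  # rerun identical
    assert classes["c0"] == "Q1_lowest" and classes["c7"] == "Q4_highest"


def test_quartiles_n10_matches_rank_rule():
    cent = {f"c{i}": float(i * i) for i in range(10)}
    classes = nm.classify_centrality_quartiles(cent)
    # rank cuts floor(10k/4): 0-1 | 2-4 | 5-6 | 7-9
    expect_sizes = {"Q1_lowest": 2, "Q2": 3, "Q3": 2, "Q4_highest": 3}
    sizes = {q: sum(v == q for v in classes.values()) for q in expect_sizes}
    assert sizes == expect_sizes
    assert classes == nm.classify_centrality_quartiles(dict(reversed(list(cent.items()))))


def test_quartiles_too_few():
    with pytest.raises(AnalysisError):
        nm.classify_centrality_quartiles({"a": 1.0, "b": 2.0, "c": 3.0})


def test_quartiles_partition(planted_500):
    _, _, _, _, _, metrics = planted_500
    counts = metrics["centrality_class"].value_counts()
    assert counts.sum() == len(metrics)
    assert counts.max() - counts.min() <= 1


def test_compute_metrics_missing_city(path_graph):
    cities, network = path_graph
    extra = make_cities([("A", 0, 0, "X", 1), ("Z", 3, 3, "X", 1)])
    with pytest.raises(AnalysisError, match="Z"):
        nm.compute_metrics(network, extra, with_centrality=False)
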