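import numpy as np
import pandas as pd
import pytest

from urbiso.data_model import UrbanNetwork, validate_cities, validate_network
from urbiso.event_assignment import AssignmentParams
from urbiso.network_metrics import compute_metrics
from urbiso.synthetic_data import SyntheticConfig, generate


def make_cities(rows):
    """rows: list of (city_id, lon, lat, country, population)."""
    df = pd.DataFrame(rows, columns=["city_id", "lon", "lat", "country", "population"])
    df.insert(1, "name", df["city_id"])
    return validate_cities(df)


def make_network(cities, edge_rows, junctions=()):
    """edge_rows: (from, to, travel_time_h) or (from, to, time, crosses_border)."""
    nodes = pd.DataFrame({
        "node_id": cities["city_id"],
        "kind": "city",
        "lon": cities["lon"],
        "lat": cities["lat"],
        "country": cities["country"],
        "city_ref": cities["city_id"],
    })
    if junctions:
        jdf = pd.DataFrame(junctions, columns=["node_id", "lon", "lat", "country"])
        jdf["kind"] = "junction"
        jdf["city_ref"] = ""
        nodes = pd.concat([nodes, jdf[nodes.columns]], ignore_index=True)
    cols = ["from_node", "to_node", "travel_time_h", "crosses_border"]
    edges = pd.DataFrame([list(r) + [None] * (4 - len(r)) for r in edge_rows],
                         columns=cols)
    if edges["crosses_border"].isna().all():
        edges = edges.drop(columns=["crosses_border"])
    return validate_network(nodes, edges, cities=cities)


@pytest.fixture
def path_graph():
    """Three unit-population cities A-B-C on 1 h edges (B-C crosses a border)."""
    cities = make_cities([
        ("A", 0.0, 0.0, "X", 1),
        ("B", 0.5, 0.0, "X", 1),
        ("C", 1.0, 0.0, "X", 1),
    ])
    network = make_network(cities, [("A", "B", 1.0), ("B", "C", 1.0)])
    return cities, network


def make_events(rows):
    """rows: list of (event_id, date, category, lon, lat, fatalities)."""
    from urbiso.data_model import validate_events
    df = pd.DataFrame(rows, columns=["event_id", "date", "category",
                                     "lon", "lat", "fatalities"])
    return validate_events(df)


# --- shared synthetic datasets (session-scoped: generation is the slow part) ---

@pytest.fixture(scope="session")
def planted_500():
    """n=500 system with isolation multiplier 5.4 and linear scaling."""
    cfg = SyntheticConfig(n_cities=500, seed=3, beta_true=1.0, alpha_true=5e-4,
                          isolation_multiplier=5.4)
    cities, network, events, truth = generate(cfg)
    metrics = compute_metrics(network, cities, with_centrality=True)
    return cfg, cities, network, events, truth, metrics


@pytest.fixture(scope="session")
def null_500():
    """n=500 null system: no isolation effect, linear scaling."""
    cfg = SyntheticConfig(n_cities=500, seed=9, beta_true=1.0, alpha_true=5e-4,
                          isolation_multiplier=1.0)
    cities, network, events, truth = generate(cfg)
    metrics = compute_metrics(network, cities, with_centrality=False)
    return cfg, cities, network, events, truth, metrics


@pytest.fixture
def default_params():
    return AssignmentParams(delta_km=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260903)
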