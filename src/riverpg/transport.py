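"""Geographic distance models and the Propagule Pressure Index (PrPI).

Three distance models over study sites: straight-line Euclidean distance on
projected planar coordinates (km), fluvial path distance along river edges,
and shortest accessible path over the combined fluvial + terrestrial
network. PrPI is a transport *similarity* between two towns: the number of
trips per vehicle type weighted by that vehicle type's probability of
carrying mosquitoes, summed over types,

    PrPI(o, d) = sum_j gamma_j * trips_j(o, d).

Infestation probabilities ship with field defaults of 0.71 for large
barges, 0.35 for medium barges and 0.125 for buses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SiteGeography",
    "TransportNetwork",
    "DistanceMatrix",
    "euclidean_matrix",
    "path_matrix",
    "propagule_pressure_index",
    "prpi_matrix",
    "DEFAULT_GAMMAS",
]

MODES = ("fluvial", "terrestrial")

#: Default per-vehicle-type infestation probabilities.
DEFAULT_GAMMAS = {"large_barge": 0.71, "medium_barge": 0.35, "bus": 0.125}


@dataclass
class SiteGeography:
    site: str
    x_km: float
    y_km: float
    human_population: int | None = None


@dataclass
class TransportNetwork:
    """Sites joined by modal edges, plus per-vehicle-type trip counts."""

    nodes: list[str]
    edges: list[tuple[str, str, str, float]]  # (u, v, mode, length_km)
    gammas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMAS))
    trips: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate site nodes")
        for u, v, mode, length in self.edges:
            if mode not in MODES:
                raise ValueError(f"unknown edge mode {mode!r}")
            if length <= 0:
                raise ValueError(f"edge {u}-{v} has non-positive length")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge {u}-{v} references unknown node")
        for vt, g in self.gammas.items():
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"gamma for {vt!r} outside [0, 1]")
        for vt, table in self.trips.items():
            if vt not in self.gammas:
                raise ValueError(f"trips given for unknown vehicle type {vt!r}")
            for (o, d), c in table.items():
                if c < 0 or int(c) != c:
                    raise ValueError(f"trip count for {o}->{d} must be a non-negative integer")

    def graph(self, modes: tuple[str, ...] = MODES) -> nx.Graph:
        if not modes:
            raise ValueError("empty mode set")
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, mode, length in self.edges:
            if mode in modes:
                if g.has_edge(u, v):
                    length = min(length, g[u][v]["length_km"])
                g.add_edge(u, v, length_km=length)
        return g


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix; PrPI matrices are similarities."""

    labels: list[str]
    values: np.ndarray
    model: str  # euclidean | fluvial_path | shortest_path | prpi
    is_similarity: bool = False
    defined: np.ndarray | None = None  # mask of pairs with data (PrPI)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite.T]):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values[finite] < 0):
            raise ValueError("entries must be non-negative")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def euclidean_matrix(geo: list[SiteGeography]) -> DistanceMatrix:
    """Planar straight-line distances in km."""
    labels = [g.site for g in geo]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate site labels")
    if len(labels) < 2:
        raise ValueError("need >= 2 sites")
    xy = np.array([[g.x_km, g.y_km] for g in geo])
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    diff = xy[:, None, :] - xy[None, :, :]
    return DistanceMatrix(labels, np.hypot(diff[..., 0], diff[..., 1]), "euclidean")


def path_matrix(net: TransportNetwork, modes: tuple[str, ...] = MODES) -> DistanceMatrix:
    """Shortest-path lengths on the mode-filtered subgraph (km).

    Unreachable pairs are flagged infinite. With ``modes=("fluvial",)`` this
    is the fluvial path distance; with both modes the shortest accessible
    route.
    """
    g = net.graph(modes)
    k = len(net.nodes)
    vals = np.full((k, k), np.inf)
    np.fill_diagonal(vals, 0.0)
    idx = {n: i for i, n in enumerate(net.nodes)}
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length_km"):
        for dst, d in lengths.items():
            vals[idx[src], idx[dst]] = d
    model = "fluvial_path" if modes == ("fluvial",) else "shortest_path"
    return DistanceMatrix(net.nodes, vals, model)


def propagule_pressure_index(net: TransportNetwork, origin: str, destination: str,
                             symmetric: bool = True) -> float:
    """Infestation-weighted trip count between two towns.

    The symmetric variant (default, required for Mantel input) sums both
    directions of travel.
    """
    total = 0.0
    for vt, table in net.trips.items():
        gamma = net.gammas[vt]
        total += gamma * table.get((origin, destination), 0)
        if symmetric:
            total += gamma * table.get((destination, origin), 0)
    return total


def prpi_matrix(net: TransportNetwork) -> DistanceMatrix:
    """Symmetric PrPI similarity matrix; ``defined`` marks pairs with trips."""
    k = len(net.nodes)
    vals = np.zeros((k, k))
    defined = np.zeros((k, k), dtype=bool)
    idx = {n: i for i, n in enumerate(net.nodes)}
    seen: set[tuple[str, str]] = set()
    for table in net.trips.values():
        seen.update(table.keys())
    for i, a in enumerate(net.nodes):
        for j, b in enumerate(net.nodes):
            if i >= j:
                continue
            v = propagule_pressure_index(net, a, b, symmetric=True)
            vals[i, j] = vals[j, i] = v
            if (a, b) in seen or (b, a) in seen:
                defined[i, j] = defined[j, i] = True
    return DistanceMatrix(net.nodes, vals, "prpi", is_similarity=True, defined=defined)


# ---------------------------------------------------------------------------
# file I/O (edge list / trips / gammas CSVs)
# ---------------------------------------------------------------------------

def read_network(edges_csv: str | Path, trips_csv: str | Path | None = None,
                 gammas_csv: str | Path | None = None) -> TransportNetwork:
    """Assemble a TransportNetwork from CSV files.

    ``edges_csv``: columns from, to, mode, length_km.
    ``trips_csv``: columns vehicle_type, from, to, n_trips.
    ``gammas_csv``: columns vehicle_type, infestation_prob (defaults used
    when omitted).
    """
    e = pd.read_csv(edges_csv)
    edges = [(r["from"], r["to"], r["mode"], float(r["length_km"]))
             for _, r in e.iterrows()]
    nodes = sorted(set(e["from"]) | set(e["to"]))
    gammas = dict(DEFAULT_GAMMAS)
    if gammas_csv is not None:
        g = pd.read_csv(gammas_csv)
        gammas = dict(zip(g["vehicle_type"], g["infestation_prob"].astype(float)))
    trips: dict[str, dict[tuple[str, str], int]] = {}
    if trips_csv is not None:
        tr = pd.read_csv(trips_csv)
        for _, r in tr.iterrows():
            trips.setdefault(r["vehicle_type"], {})[(r["from"], r["to"])] = int(r["n_trips"])
        nodes = sorted(set(nodes) | {o for t in trips.values() for od in t for o in od})
    return TransportNetwork(nodes, edges, gammas, trips)


def write_network(net: TransportNetwork, edges_csv: str | Path,
                  trips_csv: str | Path, gammas_csv: str | Path) -> None:
    pd.DataFrame([{"from": u, "to": v, "mode": m, "length_km": l}
                  for u, v, m, l in net.edges]).to_csv(edges_csv, index=False)
    pd.DataFrame([{"vehicle_type": vt, "from": o, "to": d, "n_trips": c}
                  for vt, table in net.trips.items()
                  for (o, d), c in table.items()]).to_csv(trips_csv, index=False)
    pd.DataFrame([{"vehicle_type": vt, "infestation_prob": g}
                  for vt, g in net.gammas.items()]).to_csv(gammas_csv, index=False)
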