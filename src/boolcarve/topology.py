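"""Structural statistics of (sub-)networks and random null ensembles.

Sub-networks are handled as directed graphs over the full node set. Feedback
loops are simple directed cycles of 1, 2 or 3 nodes (logic and sign
ignored); degree heterogeneity is the population variance of the total
(in+out) degree distribution divided by its mean; the characteristic path
length is the mean directed shortest-path length over reachable ordered
pairs. Connected components are counted weakly, over nodes with at least one
incident edge.

Null ensembles either delete m random edges from the full network
(random-deletion, the control for the core) or keep m randomly selected
edges (random-selection, the control for the neighbor), and compare the
observed statistic to the replicate distribution with a one-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import stats

from .decomposition import Decomposition
from .model import BooleanNetwork, Edge


def to_digraph(obj) -> nx.DiGraph:
    """Directed graph from a BooleanNetwork, an edge iterable, or a DiGraph
    (node set preserved where available)."""
    if isinstance(obj, nx.DiGraph):
        return obj
    g = nx.DiGraph()
    if isinstance(obj, BooleanNetwork):
        g.add_nodes_from(obj.nodes)
        g.add_edges_from(obj.edges)
    else:
        g.add_edges_from(obj)
    return g


def subgraph_with_nodes(net: BooleanNetwork, edges: Iterable[Edge]) -> nx.DiGraph:
    """Sub-network with the given edges and ALL nodes of the original."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(edges)
    return g


@dataclass
class TopologyStats:
    self_loops: int
    two_node_feedbacks: int
    three_node_feedbacks: int
    degree_heterogeneity: float
    characteristic_path_length: float
    n_components: int
    degree_histogram: dict[int, int]


def count_feedbacks(net, k: int) -> int:
    """Number of distinct simple directed cycles on exactly k nodes
    (each node set counted once); k in {1, 2, 3}."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    g = to_digraph(net)
    if k == 1:
        return sum(1 for u in g.nodes if g.has_edge(u, u))
    if k == 2:
        return sum(
            1 for u, v in g.edges if u < v and g.has_edge(v, u)
        )
    return sum(1 for c in nx.simple_cycles(g, length_bound=3) if len(c) == 3)


def degree_heterogeneity(net) -> float:
    """Population variance of the total-degree distribution over its mean."""
    g = to_digraph(net)
    degs = np.array([d for _, d in g.degree()], dtype=float)
    if degs.size == 0 or degs.sum() == 0:
        raise ValueError("degree heterogeneity undefined for an edge-free graph")
    return float(degs.var() / degs.mean())


def characteristic_path_length(net) -> float:
    """Mean directed shortest-path length over ordered pairs (u != v) with a
    finite distance; unreachable pairs are excluded."""
    g = to_digraph(net)
    total, n_pairs = 0, 0
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            if u != v:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no reachable ordered pairs")
    return total / n_pairs


def connected_components(net) -> int:
    """Weakly connected components among nodes with >= 1 incident edge."""
    g = to_digraph(net)
    g = g.subgraph([n for n, d in g.degree() if d > 0])
    return nx.number_weakly_connected_components(g)


def compute_stats(net) -> TopologyStats:
    g = to_digraph(net)
    degs = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    return TopologyStats(
        self_loops=count_feedbacks(g, 1),
        two_node_feedbacks=count_feedbacks(g, 2),
        three_node_feedbacks=count_feedbacks(g, 3),
        degree_heterogeneity=degree_heterogeneity(g) if g.number_of_edges() else float("nan"),
        characteristic_path_length=(
            characteristic_path_length(g) if g.number_of_edges() else float("nan")
        ),
        n_components=connected_components(g),
        degree_histogram=hist,
    )


STATISTICS = {
    "self_loops": lambda g: count_feedbacks(g, 1),
    "two_node_feedbacks": lambda g: count_feedbacks(g, 2),
    "three_node_feedbacks": lambda g: count_feedbacks(g, 3),
    "degree_heterogeneity": degree_heterogeneity,
    "characteristic_path_length": characteristic_path_length,
    "n_components": connected_components,
}


def random_deletion_subnetwork(net, m: int, seed=None) -> nx.DiGraph:
    """Uniformly delete m edges without replacement; node set retained."""
    g = to_digraph(net)
    edges = sorted(g.edges)
    if m > len(edges):
        raise ValueError(f"cannot delete {m} of {len(edges)} edges")
    rng = np.random.default_rng(seed)
    drop = rng.choice(len(edges), size=m, replace=False)
    keep = [e for i, e in enumerate(edges) if i not in set(drop.tolist())]
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(keep)
    return h


def random_selection_subnetwork(net, m: int, seed=None) -> nx.DiGraph:
    """Sub-network of m uniformly selected edges; node set retained."""
    g = to_digraph(net)
    edges = sorted(g.edges)
    if m > len(edges):
        raise ValueError(f"cannot select {m} of {len(edges)} edges")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(edges), size=m, replace=False)
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(edges[i] for i in pick)
    return h


@dataclass
class NullEnsembleResult:
    observed: float
    null_values: list[float]
    p_value: float
    direction: str
    variance_floor: bool = False


def null_comparison(
    observed_subnet,
    net,
    m: int,
    statistic: str,
    replicates: int = 100,
    direction: str = "greater",
    seed=None,
    null: str = "deletion",
) -> NullEnsembleResult:
    """Compare one sub-network statistic against a random null ensemble.

    Builds ``replicates`` random sub-networks (m-edge deletion or selection
    nulls of the full network), evaluates the named statistic on each, and
    returns the one-sided t-test p-value for the observed value lying
    ``direction`` than the null distribution. A degenerate (zero-variance)
    null is handled with a variance floor and flagged.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    fn = STATISTICS[statistic]
    observed = float(fn(to_digraph(observed_subnet)))
    rng = np.random.default_rng(seed)
    build = random_deletion_subnetwork if null == "deletion" else random_selection_subnetwork
    null_values = []
    for _ in range(replicates):
        sub = build(net, m, rng.integers(2**31))
        null_values.append(float(fn(sub)))
    arr = np.asarray(null_values)
    var = arr.var(ddof=1)
    floor = False
    if var <= 0:
        var = 1e-12
        floor = True
    t = (observed - arr.mean()) / np.sqrt(var)
    df = replicates - 1
    p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
    return NullEnsembleResult(observed, null_values, float(p), direction, floor)


def degree_bin_neighbor_ratio(
    net: BooleanNetwork,
    decomposition: Decomposition,
    bins: dict | None = None,
) -> dict:
    """Ratio of robust-neighbor incidences to all edge incidences per
    degree bin.

    ``bins`` maps a label to either a (lo, hi) total-degree range or an
    explicit node collection. Defaults: low 2-5, middle 6-9, high 10-42.
    An edge contributes once per incident binned node; bins with no
    incidences are omitted.
    """
    if bins is None:
        bins = {"low": (2, 5), "middle": (6, 9), "high": (10, 42)}
    g = to_digraph(net)
    deg = dict(g.degree())
    out: dict = {}
    for label, spec in bins.items():
        if isinstance(spec, tuple) and len(spec) == 2 and all(
            isinstance(x, int) for x in spec
        ):
            members = {v for v, d in deg.items() if spec[0] <= d <= spec[1]}
        else:
            members = set(spec)
        total = neigh = 0
        for v in members:
            incident = {e for e in net.edges if v in e}
            total += len(incident)
            neigh += len(incident & decomposition.neighbor_edges)
        if total:
            out[label] = neigh / total
    return out
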