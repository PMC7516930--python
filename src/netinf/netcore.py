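"""Graph and multilayer-network data model, I/O and shared graph algorithms.

Monolayer networks are plain :class:`networkx.Graph` / :class:`networkx.DiGraph`
objects (nodes in first-appearance order, positive edge weights under the
``"weight"`` key).  Multilayer networks are a family of layer graphs over a
shared node-identifier space plus weighted inter-layer couplings between
(node, layer) replicas; their supra-adjacency matrix is block-diagonal in the
layer adjacencies with the couplings in the off-diagonal blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MultilayerNetwork",
    "NetworkSummary",
    "read_edge_list",
    "write_edge_list",
    "read_multiplex",
    "write_multiplex",
    "supra_adjacency",
    "shortest_path_lengths",
    "connected_component_count",
    "k_shell",
    "epidemic_threshold",
    "network_summary",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file (message names the line number)."""


def _check_weight(w: float, path: str, lineno: int) -> float:
    if not (w > 0) or not math.isfinite(w):
        raise EdgeListParseError(
            f"{path}:{lineno}: edge weight must be a positive finite real, got {w!r}"
        )
    return w


def read_edge_list(path, directed: bool = False, weighted: bool = False) -> nx.Graph:
    """Read a TSV/whitespace edge list ``src dst [weight]`` into a graph.

    Lines starting with ``#`` and blank lines are skipped.  Nodes keep
    first-appearance order; a missing third field defaults to weight 1.
    Self-loops and non-positive weights raise :class:`EdgeListParseError`.
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                raise EdgeListParseError(f"{path}:{lineno}: self-loop on node {u!r}")
            w = 1.0
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight field {parts[2]!r} is not a number"
                    ) from exc
                _check_weight(w, str(path), lineno)
            elif weighted:
                pass  # weighted flag only asserts intent; absent weight stays 1
            g.add_edge(u, v, weight=w)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write ``src<TAB>dst<TAB>weight`` lines; inverse of :func:`read_edge_list`."""
    with open(path, "w") as fh:
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


@dataclass
class MultilayerNetwork:
    """A family of layer graphs plus inter-layer couplings.

    ``layers`` maps layer label -> graph, in first-appearance order (dicts
    preserve insertion order).  ``interlayer_edges`` holds
    ``((node, layer_a), (node, layer_b), weight)`` triples with
    ``layer_a != layer_b``; couplings are undirected.  The replica count
    ``N = sum_a |V_a|`` is the supra-adjacency dimension.
    """

    layers: dict[str, nx.Graph] = field(default_factory=dict)
    interlayer_edges: list[tuple[tuple[str, str], tuple[str, str], float]] = field(
        default_factory=list
    )

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_replicas(self) -> int:
        return sum(len(g) for g in self.layers.values())

    def replicas(self) -> list[tuple[str, str]]:
        """All (layer, node) replicas in layer-major, node first-appearance order."""
        return [(name, n) for name, g in self.layers.items() for n in g]

    def n_intralayer_edges(self) -> int:
        return sum(g.number_of_edges() for g in self.layers.values())

    def n_interlayer_edges(self) -> int:
        return len(self.interlayer_edges)

    def validate(self) -> None:
        for (u, la), (v, lb), w in self.interlayer_edges:
            if la == lb:
                raise ValueError(f"inter-layer edge within a single layer {la!r}")
            for node, lab in ((u, la), (v, lb)):
                if lab not in self.layers:
                    raise ValueError(f"unknown layer label {lab!r}")
                if node not in self.layers[lab]:
                    raise ValueError(f"replica ({node!r}, {lab!r}) does not exist")
            if not (w > 0):
                raise ValueError("inter-layer weight must be positive")

    def supra_graph(self) -> nx.Graph:
        """The supra-graph: one node per (layer, node) replica.

        Intra-layer edges connect replicas within a layer; inter-layer
        couplings connect replicas across layers.  Edge data records the
        coupling ``kind`` ("intra" or "inter") used by the spreading model.
        """
        sg = nx.Graph()
        sg.add_nodes_from(self.replicas())
        for name, g in self.layers.items():
            for u, v, data in g.edges(data=True):
                sg.add_edge((name, u), (name, v),
                            weight=data.get("weight", 1.0), kind="intra")
        for (u, la), (v, lb), w in self.interlayer_edges:
            sg.add_edge((la, u), (lb, v), weight=w, kind="inter")
        return sg


def read_multiplex(intra_path, inter_path=None) -> MultilayerNetwork:
    """Read a multiplex edge list (``layer src dst [weight]``) and an optional
    inter-layer coupling list (``src layerA dst layerB [weight]``).

    Layers are ordered by first appearance in the intra file.  Inter-layer
    lines referencing unknown layers, or coupling a layer to itself, raise
    :class:`EdgeListParseError`.
    """
    m = MultilayerNetwork()
    with open(intra_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise EdgeListParseError(
                    f"{intra_path}:{lineno}: expected 3 or 4 fields, got {len(parts)}"
                )
            layer, u, v = parts[0], parts[1], parts[2]
            w = _check_weight(float(parts[3]), str(intra_path), lineno) if len(parts) == 4 else 1.0
            g = m.layers.setdefault(layer, nx.Graph())
            g.add_edge(u, v, weight=w)
    if inter_path is not None:
        with open(inter_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) not in (4, 5):
                    raise EdgeListParseError(
                        f"{inter_path}:{lineno}: expected 4 or 5 fields, got {len(parts)}"
                    )
                u, la, v, lb = parts[:4]
                w = _check_weight(float(parts[4]), str(inter_path), lineno) if len(parts) == 5 else 1.0
                if la == lb:
                    raise EdgeListParseError(
                        f"{inter_path}:{lineno}: inter-layer edge within layer {la!r}"
                    )
                for lab in (la, lb):
                    if lab not in m.layers:
                        raise EdgeListParseError(
                            f"{inter_path}:{lineno}: unknown layer label {lab!r}"
                        )
                m.layers[la].add_node(u)
                m.layers[lb].add_node(v)
                m.interlayer_edges.append(((u, la), (v, lb), w))
    m.validate()
    return m


def write_multiplex(m: MultilayerNetwork, intra_path, inter_path=None) -> None:
    """Write the two-file multiplex format; inverse of :func:`read_multiplex`."""
    with open(intra_path, "w") as fh:
        for name, g in m.layers.items():
            for u, v, data in g.edges(data=True):
                fh.write(f"{name}\t{u}\t{v}\t{data.get('weight', 1.0):g}\n")
    if inter_path is not None:
        with open(inter_path, "w") as fh:
            for (u, la), (v, lb), w in m.interlayer_edges:
                fh.write(f"{u}\t{la}\t{v}\t{lb}\t{w:g}\n")


def supra_adjacency(m: MultilayerNetwork) -> np.ndarray:
    """Dense supra-adjacency matrix of a multilayer network.

    Row/column index follows :meth:`MultilayerNetwork.replicas` order
    (layer-major, then node first-appearance within layer): block-diagonal
    layer adjacencies, inter-layer coupling weights off the diagonal.
    Symmetric whenever all layers are undirected.
    """
    reps = m.replicas()
    idx = {r: i for i, r in enumerate(reps)}
    n = len(reps)
    a = np.zeros((n, n))
    for name, g in m.layers.items():
        for u, v, data in g.edges(data=True):
            w = data.get("weight", 1.0)
            i, j = idx[(name, u)], idx[(name, v)]
            a[i, j] = w
            if not g.is_directed():
                a[j, i] = w
    for (u, la), (v, lb), w in m.interlayer_edges:
        i, j = idx[(la, u)], idx[(lb, v)]
        a[i, j] = a[j, i] = w
    return a


def shortest_path_lengths(g: nx.Graph, source, cutoff: int | None = None) -> dict:
    """Hop-count distances from ``source`` to every reachable node.

    Distances are unweighted hop counts throughout this package; edge weights
    enter influence scores and spreading probabilities, never path lengths.
    """
    if source not in g:
        raise KeyError(f"unknown source node {source!r}")
    return dict(nx.single_source_shortest_path_length(g, source, cutoff=cutoff))


def connected_component_count(g: nx.Graph) -> int:
    """Number of connected components; isolated nodes count, empty graph -> 0."""
    if g.is_directed():
        return nx.number_weakly_connected_components(g)
    return nx.number_connected_components(g)


def k_shell(g: nx.Graph) -> dict:
    """k-shell (core) index of every node by iterative degree pruning."""
    if g.is_directed():
        raise nx.NetworkXNotImplemented("k-shell requires an undirected graph")
    return nx.core_number(g)


def epidemic_threshold(g: nx.Graph) -> float:
    """Heterogeneous mean-field epidemic threshold <k> / (<k^2> - <k>).

    Uses the unit-weight degree sequence.  Raises ``ValueError`` when
    ``<k^2> <= <k>`` (e.g. a perfect matching), where the estimate diverges.
    """
    deg = np.array([d for _, d in g.degree()], dtype=float)
    if deg.size == 0:
        raise ValueError("empty graph has no epidemic threshold")
    k1 = deg.mean()
    k2 = (deg**2).mean()
    if k2 <= k1:
        raise ValueError("epidemic threshold undefined: <k^2> <= <k>")
    return k1 / (k2 - k1)


@dataclass
class NetworkSummary:
    """The standard descriptive statistics of a network.

    ``avg_shortest_path`` and ``avg_clustering`` are reported on the graph
    itself when connected, otherwise on the largest connected component with
    ``connected=False`` flagging the restriction.  ``degree_heterogeneity``
    is <k^2>/<k^2>^2 (1 for regular graphs); ``assortativity`` is the Pearson
    degree-degree correlation over edges (None for regular graphs, where it
    is undefined).  For multilayer input the statistics are computed on the
    supra-graph and the layer/edge-partition counts are filled in.
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_shortest_path: float
    avg_clustering: float
    assortativity: float | None
    degree_heterogeneity: float
    epidemic_threshold: float | None
    connected: bool = True
    n_layers: int | None = None
    n_intralayer_edges: int | None = None
    n_interlayer_edges: int | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def network_summary(obj: nx.Graph | MultilayerNetwork) -> NetworkSummary:
    """Descriptive statistics for a monolayer or multilayer network."""
    if isinstance(obj, MultilayerNetwork):
        g = obj.supra_graph()
        extra = dict(
            n_layers=len(obj.layers),
            n_intralayer_edges=obj.n_intralayer_edges(),
            n_interlayer_edges=obj.n_interlayer_edges(),
        )
    else:
        g = obj
        extra = {}
    if len(g) == 0:
        raise ValueError("cannot summarize an empty graph")

    deg = np.array([d for _, d in g.degree()], dtype=float)
    k1 = deg.mean()
    k2 = (deg**2).mean()
    connected = nx.is_connected(g) if not g.is_directed() else nx.is_weakly_connected(g)
    core = g if connected else g.subgraph(max(nx.connected_components(g), key=len))
    apl = nx.average_shortest_path_length(core) if len(core) > 1 else 0.0
    try:
        bc = epidemic_threshold(g)
    except ValueError:
        bc = None
    if deg.std() == 0:
        r = None  # regular graph: degree variance 0, correlation undefined
    else:
        r = float(nx.degree_assortativity_coefficient(g))
    return NetworkSummary(
        n_nodes=len(g),
        n_edges=g.number_of_edges(),
        avg_degree=float(k1),
        avg_shortest_path=float(apl),
        avg_clustering=float(nx.average_clustering(g)),
        assortativity=r,
        degree_heterogeneity=float(k2 / k1**2),
        epidemic_threshold=bc,
        connected=connected,
        **extra,
    )
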