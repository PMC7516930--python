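"""Built-in worked-example networks and seeded synthetic generators.

The Krackhardt kite — ten office workers, eighteen acquaintance ties — is
the classic demonstration that degree, closeness and betweenness can each
crown a different node: Diane has the most ties, Fernando and Garth are
closest to everyone, and Heather brokers the only path to the tail
Heather–Ike–Jane.
"""

from __future__ import annotations

import networkx as nx

from .netcore import MultilayerNetwork

__all__ = ["kite_network", "karate_club", "toy_multilayer", "random_graph"]

KITE_EDGES = [
    ("Andre", "Beverley"), ("Andre", "Carol"), ("Andre", "Diane"),
    ("Andre", "Fernando"),
    ("Beverley", "Diane"), ("Beverley", "Ed"), ("Beverley", "Garth"),
    ("Carol", "Diane"), ("Carol", "Fernando"),
    ("Diane", "Ed"), ("Diane", "Fernando"), ("Diane", "Garth"),
    ("Ed", "Garth"),
    ("Fernando", "Garth"), ("Fernando", "Heather"),
    ("Garth", "Heather"),
    ("Heather", "Ike"),
    ("Ike", "Jane"),
]


def kite_network() -> nx.Graph:
    """The canonical 10-node, 18-edge Krackhardt kite (unit weights).

    Degree sequence in node order (Andre..Jane): 4, 4, 3, 6, 3, 5, 5, 3, 2, 1.
    """
    g = nx.Graph()
    g.add_edges_from(KITE_EDGES, weight=1.0)
    return g


def karate_club() -> nx.Graph:
    """Zachary's karate club (34 members, 78 friendship ties), unit weights."""
    g = nx.Graph()
    g.add_edges_from(nx.karate_club_graph().edges(), weight=1.0)
    return g


def toy_multilayer(L: int = 2, n: int = 10, p_intra: float = 0.3,
                   p_inter: float = 0.5, seed: int | None = None) -> MultilayerNetwork:
    """Seeded multiplex test network: L Erdős–Rényi layers over shared labels.

    Each layer is G(n, p_intra) over nodes ``"0".."n-1"``; each node couples
    to its own replica in every other layer independently with probability
    ``p_inter`` (unit weights).  Deterministic given the seed.
    """
    if not (0 <= p_intra <= 1 and 0 <= p_inter <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    import numpy as np

    rng = np.random.default_rng(seed)
    m = MultilayerNetwork()
    names = [str(a + 1) for a in range(L)]
    labels = [str(i) for i in range(n)]
    for name in names:
        g = nx.Graph()
        g.add_nodes_from(labels)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_intra:
                    g.add_edge(labels[i], labels[j], weight=1.0)
        m.layers[name] = g
    for ai in range(L):
        for bi in range(ai + 1, L):
            for lab in labels:
                if rng.random() < p_inter:
                    m.interlayer_edges.append(((lab, names[ai]), (lab, names[bi]), 1.0))
    m.validate()
    return m


def random_graph(model: str, seed: int | None = None, **params) -> nx.Graph:
    """Seeded standard random graph: er(n, p), ba(n, m) or ws(n, k, p)."""
    if model == "er":
        g = nx.gnp_random_graph(params["n"], params["p"], seed=seed)
    elif model == "ba":
        g = nx.barabasi_albert_graph(params["n"], params["m"], seed=seed)
    elif model == "ws":
        g = nx.watts_strogatz_graph(params["n"], params["k"], params["p"], seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}; expected er, ba or ws")
    h = nx.Graph()
    h.add_nodes_from(str(v) for v in g)
    h.add_edges_from((str(u), str(v)) for u, v in g.edges())
    nx.set_edge_attributes(h, 1.0, "weight")
    return h
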