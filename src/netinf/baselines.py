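"""Baseline node centralities: degree, betweenness, closeness, eigenvector,
PageRank, Katz, local clustering, and the gravity family (GR, GR+, LGR).

Normalization conventions follow the classical definitions: degree by
1/(N-1), betweenness by 2/((N-1)(N-2)) for undirected graphs, eigenvector
and Katz by the L2 norm, PageRank to sum 1.  All centralities except raw
weighted degree are computed on the unit-weight skeleton; hop-count
distances are used wherever a shortest-path length appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netcore import k_shell, shortest_path_lengths

__all__ = [
    "ScoreTable",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "pagerank",
    "katz_centrality",
    "clustering_coefficient",
    "gravity",
    "gravity_plus",
    "local_gravity",
]


@dataclass
class ScoreTable:
    """Per-node scores for one indicator, with the parameters that produced them."""

    method: str
    scores: dict
    params: dict = field(default_factory=dict)

    def __getitem__(self, node):
        return self.scores[node]

    def __iter__(self):
        return iter(self.scores)

    def __len__(self):
        return len(self.scores)

    def ranked(self) -> list:
        """Nodes by descending score; ties broken by ascending identifier."""
        return sorted(self.scores, key=lambda n: (-self.scores[n], str(n)))

    def as_series(self):
        import pandas as pd

        return pd.Series(self.scores, name=self.method)


def degree_centrality(g: nx.Graph, normalized: bool = True) -> ScoreTable:
    """Degree centrality: raw weighted degree, or unit-weight degree / (N-1)."""
    if normalized:
        if len(g) < 2:
            raise ValueError("normalized degree centrality needs at least 2 nodes")
        scores = {n: d / (len(g) - 1) for n, d in g.degree()}
    else:
        scores = {n: float(d) for n, d in g.degree(weight="weight")}
    return ScoreTable("dc", scores, {"normalized": normalized})


def betweenness_centrality(g: nx.Graph, normalized: bool = True) -> ScoreTable:
    scores = nx.betweenness_centrality(g, normalized=normalized)
    return ScoreTable("bc", dict(scores), {"normalized": normalized})


def closeness_centrality(g: nx.Graph) -> ScoreTable:
    """Closeness (N-1)/sum_j d_ij; on disconnected graphs, component-wise
    with that component's size (Wasserman–Faust style without the rescaling
    to the full graph), singleton components scoring 0."""
    scores = {}
    for comp in nx.connected_components(nx.Graph(g)) if not g.is_directed() else [set(g)]:
        sub = g.subgraph(comp)
        n = len(sub)
        for v in sub:
            if n == 1:
                scores[v] = 0.0
                continue
            total = sum(shortest_path_lengths(sub, v).values())
            scores[v] = (n - 1) / total
    return ScoreTable("cc", scores)


def eigenvector_centrality(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> ScoreTable:
    """Principal adjacency eigenvector, L2-normalized, all entries >= 0."""
    raw = nx.eigenvector_centrality(g, tol=tol, max_iter=max_iter)
    norm = math.sqrt(sum(v * v for v in raw.values()))
    return ScoreTable("ec", {n: v / norm for n, v in raw.items()}, {"tol": tol})


def pagerank(g: nx.Graph, damping: float = 1.0, tol: float = 1e-10,
             max_iter: int = 1000) -> ScoreTable:
    """PageRank fixed point; damping 1.0 gives the pure adjacency recursion
    (no teleport term), the conventional choice being 0.85.  Scores sum to 1;
    dangling nodes redistribute uniformly."""
    if not (0 < damping <= 1):
        raise ValueError("damping must be in (0, 1]")
    scores = nx.pagerank(g, alpha=damping, tol=tol, max_iter=max_iter, weight=None)
    return ScoreTable("pr", dict(scores), {"damping": damping})


def katz_centrality(g: nx.Graph, alpha: float = 0.1, beta: float = 1.0) -> ScoreTable:
    """Katz centrality x = alpha*A*x + beta*1, L2-normalized.

    alpha must stay below 1/lambda_max or the series diverges.
    """
    if g.number_of_edges() > 0:
        lam = max(abs(np.linalg.eigvalsh(nx.to_numpy_array(g, weight=None))))
        if lam > 0 and alpha >= 1 / lam:
            raise ValueError(
                f"alpha={alpha} >= 1/lambda_max={1 / lam:.4f}: Katz series diverges"
            )
    scores = nx.katz_centrality(g, alpha=alpha, beta=beta, normalized=True, weight=None)
    return ScoreTable("katz", dict(scores), {"alpha": alpha, "beta": beta})


def clustering_coefficient(g: nx.Graph) -> ScoreTable:
    """Local clustering coefficient: triangles / wedges, 0 below degree 2."""
    scores = nx.clustering(nx.Graph(g))
    return ScoreTable("cluster", dict(scores))


def gravity(g: nx.Graph) -> ScoreTable:
    """Gravity centrality G(i) = sum over nodes within 3 hops of
    ks(i)*ks(j)/d_ij^2, with ks the k-shell index."""
    ks = k_shell(g)
    scores = {}
    for i in g:
        dist = shortest_path_lengths(g, i, cutoff=3)
        scores[i] = sum(
            ks[i] * ks[j] / d**2 for j, d in dist.items() if 0 < d <= 3
        )
    return ScoreTable("gr", scores)


def gravity_plus(g: nx.Graph) -> ScoreTable:
    """Extended gravity G+(i) = sum of G(j) over the direct neighbors of i."""
    gr = gravity(g)
    scores = {i: sum(gr[j] for j in g[i]) for i in g}
    return ScoreTable("grplus", scores)


def local_gravity(g: nx.Graph, R: int | str = "auto") -> ScoreTable:
    """Local-gravity centrality LGR(i) = sum_{0<d_ij<=R} k_i*k_j/d_ij^2.

    ``R="auto"`` uses ceil(diameter/2), the diameter taken on the largest
    connected component.
    """
    if R == "auto":
        comp = max(nx.connected_components(nx.Graph(g)), key=len)
        R = max(1, math.ceil(nx.diameter(g.subgraph(comp)) / 2))
    if not (isinstance(R, int) and R >= 1):
        raise ValueError("R must be a positive integer or 'auto'")
    deg = dict(g.degree())
    scores = {}
    for i in g:
        dist = shortest_path_lengths(g, i, cutoff=R)
        scores[i] = sum(deg[i] * deg[j] / d**2 for j, d in dist.items() if d > 0)
    return ScoreTable("lgr", scores, {"R": R})
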