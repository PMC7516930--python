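"""Evaluation experiments: Kendall-tau agreement with SIR ground truth,
targeted node-removal robustness curves, and top-k seeding spread curves.

The ranking-agreement statistic is Kendall's tau-a,
tau = (N_c - N_d) / (n(n-1)/2), where tied pairs in either sequence are
neither concordant nor discordant: ties attenuate |tau| rather than being
renormalized away (as tau-b would).  Indicators that assign many equal
scores — degree centrality on homogeneous networks, for instance — are
therefore penalized for their inability to discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .baselines import ScoreTable
from .epidemic import SIRConfig, _contact_structure, _run, epidemic_threshold
from .influence import top_k
from .netcore import connected_component_count

__all__ = [
    "RankingComparison",
    "RemovalCurve",
    "TopKCurve",
    "kendall_tau",
    "sir_ground_truth",
    "tau_benchmark",
    "removal_curve",
    "topk_spread",
]


@dataclass
class RankingComparison:
    """Tau-a agreement between an indicator and a reference ranking."""

    indicator: str
    tau: float
    n_concordant: int
    n_discordant: int
    n: int
    protocol: dict = field(default_factory=dict)


def kendall_tau(x, y, indicator: str = "", protocol: dict | None = None) -> RankingComparison:
    """Kendall's tau-a between two aligned score sequences.

    Pairs tied in either sequence count as neither concordant nor
    discordant; the denominator stays n(n-1)/2, so ties pull tau toward 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(n, k=1)
    nc = int((prod[iu] > 0).sum())
    nd = int((prod[iu] < 0).sum())
    tau = (nc - nd) / (0.5 * n * (n - 1))
    return RankingComparison(indicator, float(tau), nc, nd, n, protocol or {})


def sir_ground_truth(g: nx.Graph, cfg: SIRConfig,
                     rng: np.random.Generator | None = None) -> ScoreTable:
    """Reference spreading-influence ranking: every node seeded in turn.

    Each node's influence is its mean P(i) = N_R / N over ``cfg.n_runs``
    independent SIR runs seeded at that node alone.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nodes, idx, nbrs, probs = _contact_structure(g, cfg.beta)
    n = len(nodes)
    scores = {}
    for node in nodes:
        s = idx[node]
        total = 0
        for _ in range(cfg.n_runs):
            rec, _steps = _run([s], n, nbrs, probs, cfg.gamma, rng)
            total += rec
        scores[node] = total / (cfg.n_runs * n)
    return ScoreTable("sir_ground_truth", scores,
                      {"beta": cfg.beta, "gamma": cfg.gamma, "n_runs": cfg.n_runs})


def tau_benchmark(g: nx.Graph, indicators: dict[str, ScoreTable], cfg: SIRConfig,
                  rng: np.random.Generator | None = None,
                  ground_truth: ScoreTable | None = None) -> list[RankingComparison]:
    """Tau-a of each indicator against one shared SIR ground-truth ranking.

    ``indicators`` maps a name to a precomputed :class:`ScoreTable` covering
    the graph's nodes; a ground truth may be passed in to be reused across
    calls, otherwise it is simulated here.
    """
    if ground_truth is None:
        ground_truth = sir_ground_truth(g, cfg, rng)
    nodes = list(g)
    x = [ground_truth[nd] for nd in nodes]
    protocol = {"beta": cfg.beta, "gamma": cfg.gamma, "n_runs": cfg.n_runs,
                "seed": cfg.seed}
    out = []
    for name, table in indicators.items():
        y = [table[nd] for nd in nodes]
        out.append(kendall_tau(x, y, indicator=name, protocol=protocol))
    return out


@dataclass
class RemovalCurve:
    """Subgraph counts along a targeted-removal trajectory."""

    indicator: str
    removal_order: list
    counts: list[int]  # length N+1: initial count, then after each removal

    @property
    def peak(self) -> int:
        return max(self.counts)


def removal_curve(g: nx.Graph, scores: ScoreTable,
                  score_fn=None) -> RemovalCurve:
    """Remove nodes in descending score and record the component count.

    The removal order is static by default: scores are computed once on the
    intact graph and nodes deleted one at a time in descending score, ties
    broken by ascending identifier.  Passing ``score_fn`` (a callable
    graph -> ScoreTable) switches to adaptive targeting, re-scoring the
    surviving graph before each deletion.  Removed nodes are deleted, not
    isolated, so the curve rises while edges persist and falls back to 0
    once every node is gone.
    """
    missing = [n for n in g if n not in scores.scores]
    if missing:
        raise ValueError(f"scores missing for nodes: {missing[:5]!r}")
    h = g.copy()
    counts = [connected_component_count(h)]
    order = []
    if score_fn is None:
        for n in [v for v in scores.ranked() if v in g]:
            h.remove_node(n)
            order.append(n)
            counts.append(connected_component_count(h))
    else:
        while len(h):
            n = score_fn(h).ranked()[0]
            h.remove_node(n)
            order.append(n)
            counts.append(connected_component_count(h))
    return RemovalCurve(scores.method, order, counts)


@dataclass
class TopKCurve:
    """Mean final spread for top-k seed sets of each indicator."""

    k_fractions: list[float]
    k_values: list[int]
    mean_recovered: dict[str, list[float]]  # indicator -> per-k means
    beta: float
    beta_ratio: float
    protocol: dict = field(default_factory=dict)


def topk_spread(g: nx.Graph, indicators: dict[str, ScoreTable],
                k_fractions=(0.05, 0.10, 0.15, 0.20),
                beta_ratio: float = 1.5,
                cfg: SIRConfig | None = None,
                rng: np.random.Generator | None = None) -> TopKCurve:
    """Seed the top-k nodes of each indicator and measure the mean spread.

    The infection probability is ``beta_ratio`` times the epidemic threshold
    of the graph, clipped to [0, 1].  For each k fraction the k highest
    scorers (ties by identifier) are infected simultaneously and
    ``cfg.n_runs`` SIR runs are averaged.
    """
    cfg = cfg or SIRConfig()
    beta = min(1.0, beta_ratio * epidemic_threshold(g))
    run_cfg = SIRConfig(beta=beta, gamma=cfg.gamma, n_runs=cfg.n_runs, seed=cfg.seed)
    if rng is None:
        rng = np.random.default_rng(run_cfg.seed)
    n = len(g)
    ks = []
    for f in k_fractions:
        k = max(1, round(f * n))
        if k > n:
            raise ValueError(f"k fraction {f} exceeds the node count")
        ks.append(k)
    nodes_all, idx, nbrs, probs = _contact_structure(g, beta)
    means: dict[str, list[float]] = {}
    for name, table in indicators.items():
        per_k = []
        for k in ks:
            seeds = [idx[nd] for nd in top_k(table, k)]
            total = 0
            for _ in range(run_cfg.n_runs):
                rec, _steps = _run(seeds, n, nbrs, probs, run_cfg.gamma, rng)
                total += rec
            per_k.append(total / run_cfg.n_runs)
        means[name] = per_k
    return TopKCurve(list(k_fractions), ks, means, beta, beta_ratio,
                     {"gamma": run_cfg.gamma, "n_runs": run_cfg.n_runs,
                      "seed": run_cfg.seed})
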