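"""Discrete-time SIR spreading on monolayer and multilayer networks.

The simulator is synchronous (generation-based): in each step every
infectious node attempts to infect each of its susceptible neighbors
independently, with per-contact probability min(1, w_ij * beta), and then
recovers with probability gamma.  Recovery is applied after that step's
infection attempts, so with gamma = 1 every node transmits during exactly
one step.  A run ends when no infectious nodes remain; the seed always ends
recovered, so the final recovered count is at least the seed-set size.

On a multilayer network the same dynamics run on the supra-graph, with the
inter-layer couplings carrying the transmission probability w_ij * beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .baselines import ScoreTable
from .netcore import MultilayerNetwork, epidemic_threshold

__all__ = [
    "SIRConfig",
    "SIROutcome",
    "sir_run",
    "spread_estimate",
    "sir_run_multilayer",
    "epidemic_threshold",
]


@dataclass
class SIRConfig:
    """SIR simulation parameters.

    beta: per-contact infection probability per step, in [0, 1].
    gamma: per-step recovery probability, in (0, 1]; 1 means a node is
        infectious for exactly one step.
    n_runs: independent repetitions aggregated by :func:`spread_estimate`.
    seed: RNG seed; identical seed replays runs bit-exactly.
    """

    beta: float = 0.35
    gamma: float = 1.0
    n_runs: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class SIROutcome:
    """Aggregated spreading results for one seed (or seed set)."""

    recovered: np.ndarray  # final recovered count per run
    iterations: np.ndarray  # synchronous steps per run
    n_nodes: int
    config: SIRConfig

    @property
    def mean_recovered(self) -> float:
        return float(self.recovered.mean())

    @property
    def se_recovered(self) -> float:
        n = len(self.recovered)
        return float(self.recovered.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def mean_iterations(self) -> float:
        return float(self.iterations.mean())

    @property
    def influence(self) -> float:
        """P(i) = N_R / N, the mean recovered fraction."""
        return self.mean_recovered / self.n_nodes


def _contact_structure(g: nx.Graph, beta: float):
    """Index nodes and precompute per-contact transmission probabilities."""
    nodes = list(g)
    idx = {n: i for i, n in enumerate(nodes)}
    nbrs: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    for n in nodes:
        js, ps = [], []
        for j, data in g[n].items():
            js.append(idx[j])
            ps.append(min(1.0, data.get("weight", 1.0) * beta))
        nbrs.append(np.array(js, dtype=np.intp))
        probs.append(np.array(ps))
    return nodes, idx, nbrs, probs


def _run(seed_idx, n, nbrs, probs, gamma, rng):
    # states: 0 susceptible, 1 infectious, 2 recovered
    state = np.zeros(n, dtype=np.int8)
    infected = list(seed_idx)
    state[infected] = 1
    steps = 0
    while infected:
        steps += 1
        new_infected = []
        for i in infected:
            js, ps = nbrs[i], probs[i]
            if len(js):
                hits = js[(state[js] == 0) & (rng.random(len(js)) < ps)]
                for j in hits:
                    state[j] = 1
                    new_infected.append(j)
        still = []
        for i in infected:
            if gamma >= 1.0 or rng.random() < gamma:
                state[i] = 2
            else:
                still.append(i)
        infected = still + new_infected
    return int((state == 2).sum()), steps


def sir_run(g: nx.Graph, seeds, cfg: SIRConfig, rng: np.random.Generator):
    """One SIR realization from the given seed set.

    Returns ``(recovered_set, steps)``.  The recovered set always contains
    the seeds; ``steps`` counts synchronous update steps until no infectious
    node remains, including the step of the last recovery.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be nonempty")
    missing = [s for s in seeds if s not in g]
    if missing:
        raise ValueError(f"seed nodes not in graph: {missing!r}")
    nodes, idx, nbrs, probs = _contact_structure(g, cfg.beta)
    return _run_labeled(g, seeds, cfg, rng, nodes, idx, nbrs, probs)


def _run_labeled(g, seeds, cfg, rng, nodes, idx, nbrs, probs):
    state = np.zeros(len(nodes), dtype=np.int8)
    infected = [idx[s] for s in seeds]
    state[infected] = 1
    steps = 0
    while infected:
        steps += 1
        new_infected = []
        for i in infected:
            js, ps = nbrs[i], probs[i]
            if len(js):
                hits = js[(state[js] == 0) & (rng.random(len(js)) < ps)]
                for j in hits:
                    state[j] = 1
                    new_infected.append(j)
        still = []
        for i in infected:
            if cfg.gamma >= 1.0 or rng.random() < cfg.gamma:
                state[i] = 2
            else:
                still.append(i)
        infected = still + new_infected
    recovered = {nodes[i] for i in np.flatnonzero(state == 2)}
    return recovered, steps


def spread_estimate(g: nx.Graph, seed, cfg: SIRConfig,
                    rng: np.random.Generator | None = None) -> SIROutcome:
    """Monte-Carlo estimate of a single node's spreading influence.

    Aggregates ``cfg.n_runs`` independent SIR runs seeded at ``seed`` and
    reports the per-run recovered counts and step counts.
    """
    if seed not in g:
        raise ValueError(f"seed node {seed!r} not in graph")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nodes, idx, nbrs, probs = _contact_structure(g, cfg.beta)
    s = idx[seed]
    rec = np.empty(cfg.n_runs, dtype=np.int64)
    its = np.empty(cfg.n_runs, dtype=np.int64)
    for r in range(cfg.n_runs):
        rec[r], its[r] = _run([s], len(nodes), nbrs, probs, cfg.gamma, rng)
    return SIROutcome(rec, its, len(nodes), cfg)


def spread_estimate_set(g: nx.Graph, seeds, cfg: SIRConfig,
                        rng: np.random.Generator | None = None) -> SIROutcome:
    """Monte-Carlo spreading estimate for a simultaneously seeded node set."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be nonempty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nodes, idx, nbrs, probs = _contact_structure(g, cfg.beta)
    si = [idx[s] for s in seeds]
    rec = np.empty(cfg.n_runs, dtype=np.int64)
    its = np.empty(cfg.n_runs, dtype=np.int64)
    for r in range(cfg.n_runs):
        rec[r], its[r] = _run(si, len(nodes), nbrs, probs, cfg.gamma, rng)
    return SIROutcome(rec, its, len(nodes), cfg)


def sir_run_multilayer(m: MultilayerNetwork, seeds, cfg: SIRConfig,
                       rng: np.random.Generator,
                       count_physical: bool = False):
    """One SIR realization on the supra-graph of a multilayer network.

    ``seeds`` are (layer, node) replicas.  Intra-layer and inter-layer
    contacts both transmit with probability min(1, w_ij * beta) — unit
    intra-layer weights give the plain beta.  Returns ``(recovered, steps)``
    where ``recovered`` holds replicas, or distinct physical nodes when
    ``count_physical`` is set.
    """
    sg = m.supra_graph()
    recovered, steps = sir_run(sg, seeds, cfg, rng)
    if count_physical:
        recovered = {node for _, node in recovered}
    return recovered, steps
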