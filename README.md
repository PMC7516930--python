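# netinf

Influential-spreader identification in monolayer and multilayer networks,
built around the **INF node-influence indicator**: a purely local centrality
that scores a node by the attention it receives from its neighborhood,

```
raw(i) = Σ_{0 < d_ij ≤ R}  w_ij / k_j        (R = 1 by default)
INF(i) = 1 / (1 + exp(−raw(i)))
```

where `k_j` is the degree of neighbor `j`, `w_ij` the edge weight (1 for
unweighted networks) and `d_ij` the hop distance. A neighbor divides its
unit of attention among its `k_j` contacts, so a pendant neighbor
contributes 1 while a hub neighbor contributes almost nothing; the logistic
map squashes the sum into (0, 1). On a multilayer network the same sum runs
over the supra-graph, so a replica collects `w_ij / k_j` through intra-layer
edges and inter-layer couplings alike. The cost is O(n + d^R) — degree-like,
far below betweenness or closeness — which is the point: rank spreaders in
large multi-relation social networks without global computation.

The package is aimed at network scientists and epidemic modellers who need
to (a) rank nodes by spreading power, (b) validate a ranking against SIR
simulation ground truth, and (c) do both on multiplex/multilayer data. It
ships the classical baselines (degree, betweenness, closeness, eigenvector,
PageRank, Katz, clustering, gravity GR/GR+, local gravity LGR), a
discrete-time SIR simulator with the epidemic-threshold estimate
β_c ≈ ⟨k⟩/(⟨k²⟩−⟨k⟩), Kendall tau-a ranking agreement, targeted-removal
robustness curves, and top-k seeding experiments — plus built-in worked
examples (the Krackhardt kite, Zachary's karate club) and seeded synthetic
generators so everything runs without downloads.

## Worked example

```python
from netinf import kite_network, inf_scores, top_k

g = kite_network()          # 10 actors, 18 ties
inf = inf_scores(g)         # R=1, logistic normalization
print({n: round(inf[n], 4) for n in g})
print(top_k(inf, 4))
```

prints

```
{'Andre': 0.7211, 'Beverley': 0.7211, 'Carol': 0.6495, 'Diane': 0.8273,
 'Fernando': 0.783, 'Ed': 0.6495, 'Garth': 0.783, 'Heather': 0.7109,
 'Ike': 0.7914, 'Jane': 0.6225}
['Diane', 'Ike', 'Fernando', 'Garth']
```

Diane — six neighbors, each of low-to-middling degree — scores highest
(raw sum 1/4+1/4+1/3+1/3+1/5+1/5 = 1.5667, logistic 0.8273), and 10,000
SIR runs at β = 0.35, γ = 1 confirm she is the strongest spreader (mean
outbreak 5.29 of 10 nodes, vs 1.80 when seeding the pendant Jane). Note the
indicator's local blind spot: Ike ranks second because his pendant neighbor
Jane contributes a full 1/1, yet his simulated spreading power is ninth.

The `examples/` directory holds one short script per capability — kite
ranking, SIR spreading estimates, multilayer INF on a toy multiplex, and
the three validation experiments on the karate club — each printing the
numbers it computes and a line on what they mean.

A thin CLI mirrors the library for shell use:

```
netinf fixtures kite --out kite.tsv
netinf rank kite.tsv --method inf
netinf sir kite.tsv --seed-node Diane --beta 0.35 --runs 10000 --rng-seed 42
netinf evaluate tau kite.tsv --methods dc,bc,cc,lgr,inf --rng-seed 42
netinf stats kite.tsv
```

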