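# Methods

## The INF indicator

INF treats influence as energy drawn from the neighborhood. For node `i`
with truncation radius `R`:

```
raw(i) = Σ_{j : 0 < d_ij ≤ R} f(d_ij) · w_ij / k_j
INF(i) = logistic(raw(i)) = 1 / (1 + e^{−raw(i)})
```

- `k_j` — degree of the contributing node `j` (unit-weight degree). Each
  node divides its attention among its `k_j` contacts: a pendant neighbor
  contributes 1, a hub neighbor ~0.
- `w_ij` — edge weight, 1 on unweighted networks. Only the weight of the
  direct edge enters; weights never alter distances.
- `d_ij` — hop count. At the default `R = 1` every contributing distance is
  1 and `f` is irrelevant. For `R > 1` the distance factor defaults to the
  gravity-family decay `f(d) = 1/d²` (`distance_weight="denominator"`); the
  alternative reading `f(d) = d²` is exposed because the flattened fraction
  in the defining formula is ambiguous and the recommended setting `R = 1`
  never exercises it.
- Normalization: the raw sums on the Krackhardt kite (Diane 1.5667, Jane
  0.5) only match the published per-node values after the logistic map —
  applying `1/(1+e^{−x})` reproduces all seven distinct kite values to 4
  decimals (0.8273, 0.7914, 0.7830, 0.7211, 0.7109, 0.6495, 0.6225) — so
  logistic is the default; `norm="raw"` is kept for transparency. The map is
  strictly monotone, so both modes induce the identical ranking and
  identical tau against any reference (tested).

### Multilayer INF

A multilayer network is a family of layer graphs `G_α` plus inter-layer
couplings between (node, layer) replicas; its supra-adjacency matrix is
block-diagonal in the layer adjacencies with couplings off-diagonal
(layer-major, first-appearance replica ordering — stable and documented).
Multilayer INF runs the same sum on the supra-graph: at `R = 1` a replica
collects `w_ij / k_j` from every replica one intra-layer edge or one
coupling away. The degree of a contributing replica is a genuine modelling
choice:

- `degree_mode="supra"` (default): intra-layer edges plus inter-layer
  couplings — intra- and inter-layer contacts on equal footing, making
  multilayer INF exactly monolayer INF on the supra-graph.
- `degree_mode="intra"`: only the edges inside the replica's own layer
  (couplings carry contributions but do not dilute them); a replica with no
  intra-layer edges falls back to its supra-degree to avoid division by
  zero.

With one layer and no couplings both modes reduce exactly to monolayer INF
(tested).

## Baseline centralities

Degree, betweenness, closeness, eigenvector, PageRank, Katz and local
clustering delegate to networkx; the gravity family is implemented here.
Conventions, all pinned by the kite reference table:

- degree normalized by `1/(N−1)`; betweenness by `2/((N−1)(N−2))` with
  endpoints excluded; eigenvector and Katz L2-normalized.
- closeness `(N−1)/Σ d_ij` on connected graphs; on disconnected input it is
  computed per component with that component's size (documented deviation —
  the literal formula is undefined there).
- PageRank implements the damped recursion with **default damping 1.0**,
  i.e. the pure adjacency recursion with no teleport term; 0.85 is the
  conventional option. Scores sum to 1.
- Katz `x = αAx + β1` with defaults `α = 0.1, β = 1.0`, which reproduce the
  kite reference column exactly; `α ≥ 1/λ_max` is rejected.
- gravity `G(i) = Σ_{d≤3} ks(i)·ks(j)/d²` with k-shell indices;
  `G+(i) = Σ_{j∈Γ(i)} G(j)`; local gravity
  `LGR(i) = Σ_{0<d≤R} k_i·k_j/d²` with `R = ⌈diameter/2⌉` when "auto"
  (diameter on the largest component).
- All indicators run on the unit-weight skeleton except raw degree; no
  weighted variants of the classical measures are defined here.

## SIR spreading model

Discrete-time, synchronous (generation-based): in each step every
infectious node attempts each susceptible neighbor independently with
probability `min(1, w_ij · β)`, then recovers with probability `γ`
(default 1, so each node transmits during exactly one step). Seeds count as
recovered, so final outbreak size ≥ seed-set size. "Iterations" is the
number of synchronous steps until no infectious node remains, including the
step of the last recovery: a deterministic β=1 wave across the kite from
Diane takes 5 steps — 4 transmission generations plus the closing recovery.
This convention matches the published mean-iteration magnitudes but those
are treated as diagnostics, since the counting rule is not fully pinned.

On multilayer networks the dynamics run on the supra-graph; inter-layer
couplings transmit with `min(1, w_ij · β)` — the same rule as weighted
intra-layer edges, chosen for uniformity.

Spreading influence of node `i` is `P(i) = N_R / N`, the mean recovered
fraction over `n_runs` independent runs seeded at `i`. The epidemic
threshold is the heterogeneous mean-field estimate
`β_c ≈ ⟨k⟩/(⟨k²⟩−⟨k⟩)` (undefined when `⟨k²⟩ ≤ ⟨k⟩`, e.g. perfect
matchings — rejected with an error).

All randomness flows through a `numpy.random.Generator`; a fixed seed
replays any experiment bit-exactly (tested).

## Evaluation experiments

- **Kendall tau-a**, `τ = (N_c − N_d) / (n(n−1)/2)`: tied pairs in either
  sequence are neither concordant nor discordant and the denominator is not
  corrected for them, so ties attenuate |τ| — deliberately, as indicators
  with many tied scores (degree on homogeneous graphs) cannot discriminate
  spreaders. This is tau-a, not scipy's tau-b; the implementation is checked
  against a brute-force pair-enumeration oracle up to n = 50 and against
  scipy on tie-free inputs.
- **Ground truth**: every node seeded in turn, `n_runs` independent
  estimates of `P(i)` per node (default 1000 at β = 0.35, γ = 1).
- **Targeted removal**: nodes deleted one at a time in descending score
  (static order computed once on the intact graph, ties by ascending
  identifier; adaptive re-scoring available via `score_fn`), recording the
  number of connected components after each deletion. Removed nodes are
  deleted, not isolated — the curve rises until no edges remain, then falls
  to 0; it has N+1 points including the initial count.
- **Top-k seeding**: the top-k nodes of each indicator (k as a fraction of
  N) are infected simultaneously at `β = ratio · β_c` (default ratio 1.5,
  clipped to [0, 1], always logged) and the mean final outbreak size over
  `n_runs` runs is recorded.

## Synthetic data and fixtures

The Krackhardt kite (10 nodes, 18 edges) and Zachary's karate club
(34 nodes, 78 edges) are bundled as canonical worked examples; both are
pinned by their published per-node values and summary statistics in the
test suite. Generators (`er`, `ba`, `ws` monolayer models;
`toy_multilayer` — L Erdős–Rényi layers over shared labels with replica
couplings drawn with probability `p_inter`) are seed-deterministic and
label-stable. They emulate the size and density regimes of small social
networks, not degree-correlated, clustered or community-structured real
data — passing property tests on them demonstrates correctness of the
computations, not real-world ranking performance, which is
dataset-dependent (see limitations).

Test and example problem sizes (10–60 nodes, 10³–10⁴ SIR runs) were chosen
as the smallest at which Monte-Carlo error is well below the effects being
checked; the 10,000-run kite protocol reproduces the published spreading
means within 3 standard errors.

## Known limitations

- INF's locality is also its blind spot: a node whose neighbors are
  low-degree scores high regardless of its global position. On the kite,
  Ike (bridge to the pendant Jane) has the second-highest INF but only the
  ninth-highest simulated spreading power, and degree centrality achieves a
  higher tau there despite its ties. The indicator's published advantage is
  on larger, heterogeneous networks; the kite shows the mechanism, not the
  benchmark.
- Tau-a on heavily tied indicators is attenuated by construction; compare
  decided-pair counts, not just τ, when diagnosing an indicator.
- The multilayer ⟨d⟩ and clustering summary statistics are computed on the
  supra-graph (aggregation is an alternative some authors use).
- No combinatorial influence maximization: top-k selection is by score, not
  greedy marginal gain; overlapping spheres of influence of the top-k set
  are not deduplicated.
- Continuous-time (Gillespie) dynamics, SIS/SEIR variants, temporal layers
  and layer-importance weighting are out of scope.
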