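"""Rank the Krackhardt kite by the classical centralities and by INF.

The kite is the textbook case where indicators disagree: Diane has the most
ties, Fernando/Garth are closest to everyone, Heather brokers the bridge to
the tail.  INF crowns Diane but also promotes Ike, whose single pendant
neighbor (Jane) contributes its full 1/k_j = 1 to his score.
"""

from netinf import (
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    inf_scores,
    kite_network,
    top_k,
)

g = kite_network()
tables = {
    "degree": degree_centrality(g),
    "betweenness": betweenness_centrality(g),
    "closeness": closeness_centrality(g),
    "eigenvector": eigenvector_centrality(g),
    "INF": inf_scores(g),
}

header = f"{'node':<10}" + "".join(f"{m:>13}" for m in tables)
print(header)
for n in g:
    print(f"{n:<10}" + "".join(f"{t[n]:>13.4f}" for t in tables.values()))

print("\ntop-4 by INF:", top_k(tables["INF"], 4))
print("INF in (0.5, 1) for connected nodes; the ranking, not the magnitude, "
      "is what the indicator is for.")
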