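import networkx as nx
import pytest

from netinf import kite_network

# Published per-node reference values for the Krackhardt kite, to 4 decimals.
KITE_REFERENCE = {
    #            DC      BC      CC      Katz    EC      INF
    "Andre":    (0.4444, 0.0231, 0.5294, 0.3307, 0.3522, 0.7211),
    "Beverley": (0.4444, 0.0231, 0.5294, 0.3307, 0.3522, 0.7211),
    "Carol":    (0.3333, 0.0000, 0.5000, 0.3006, 0.2858, 0.6495),
    "Diane":    (0.6667, 0.1019, 0.6000, 0.3907, 0.4810, 0.8273),
    "Ed":       (0.3333, 0.0000, 0.5000, 0.3006, 0.2858, 0.6495),
    "Fernando": (0.5556, 0.2315, 0.6429, 0.3595, 0.3977, 0.7830),
    "Garth":    (0.5556, 0.2315, 0.6429, 0.3595, 0.3977, 0.7830),
    "Heather":  (0.3333, 0.3889, 0.6000, 0.2887, 0.1959, 0.7109),
    "Ike":      (0.2222, 0.2222, 0.4286, 0.2431, 0.0481, 0.7914),
    "Jane":     (0.1111, 0.0000, 0.3103, 0.2168, 0.0112, 0.6225),
}

KITE_DEGREES = {"Andre": 4, "Beverley": 4, "Carol": 3, "Diane": 6, "Ed": 3,
                "Fernando": 5, "Garth": 5, "Heather": 3, "Ike": 2, "Jane": 1}

# Structural equivalence classes of the kite (automorphism orbits).
KITE_ORBITS = [("Andre", "Beverley"), ("Carol", "Ed"), ("Fernando", "Garth")]


@pytest.fixture(scope="session")
def kite() -> nx.Graph:
    return kite_network()


@pytest.fixture()
def path3() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")], weight=1.0)
    return g
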