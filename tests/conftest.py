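import networkx as nx
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from mlpr.pair_features import EvidenceBundle


def _tiny_dag() -> nx.DiGraph:
    # child -> parent; GO:L1 is a leaf under GO:T1; GO:T2 a sibling branch
    dag = nx.DiGraph()
    for term in ("GO:R", "GO:T1", "GO:T2", "GO:L1"):
        dag.add_node(term, namespace="molecular_function")
    dag.add_edge("GO:T1", "GO:R")
    dag.add_edge("GO:T2", "GO:R")
    dag.add_edge("GO:L1", "GO:T1")
    return dag


@pytest.fixture()
def tiny_bundle() -> EvidenceBundle:
    """Hand-built four-protein bundle with known feature values."""
    expression = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 5.0],
            "s2": [2.0, 4.0, 2.0, 5.0],
            "s3": [3.0, 6.0, 1.0, 5.0],
        },
        index=["A", "B", "C", "D"],
    )
    return EvidenceBundle(
        go={"MF": {"A": frozenset({"GO:L1"}),
                   "B": frozenset({"GO:L1"}),
                   "C": frozenset({"GO:T2"})}},
        slims={"MF": {"A": frozenset({"S1"}),
                      "B": frozenset({"S1", "GO:R"}),
                      "C": frozenset({"S2"}),
                      "D": frozenset({"GO:R"})}},
        dag=_tiny_dag(),
        aspect_roots={"MF": frozenset({"GO:R"}),
                      "BP": frozenset(), "CC": frozenset()},
        expression=expression,
        domains={"A": frozenset({"d1", "d2"}), "B": frozenset({"d3"})},
        ddi={("d1", "d3"): 0.4, ("d2", "d3"): 0.6},
        string_scores={("A", "B"): 0.5},
        tap=({("A", "B"): 0.9}, {}, {}, {}, {("A", "C"): 0.3}),
        eppi=(frozenset({("A", "B")}), frozenset({("A", "C")})),
        topology={"A": frozenset({"B", "C"}), "B": frozenset({"A"}),
                  "C": frozenset({"A"})},
    )
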