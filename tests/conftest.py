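import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutnet import AbundanceTable, DependencyNetwork, InteractionMatrix, PairGrowthRecord


@pytest.fixture
def toy_records():
    """Complete 3-species pair table under both diets (6 records)."""
    species = ["spA", "spB", "spC"]
    records = []
    for diet in ("western", "high_fiber"):
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                records.append(
                    PairGrowthRecord(
                        organism_a=a, organism_b=b, diet=diet,
                        single_a=0.5, single_b=0.4, paired_a=1.0, paired_b=0.2,
                    )
                )
    return records


def make_abundance(data: dict, n_patient: int, n_control: int) -> AbundanceTable:
    """AbundanceTable from species -> per-sample values (fractions).

    The first ``n_patient`` columns are patient samples.
    """
    samples = [f"p{i}" for i in range(n_patient)] + [f"c{i}" for i in range(n_control)]
    frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    groups = {s: ("patient" if s.startswith("p") else "control") for s in samples}
    return AbundanceTable(frame, groups)


def matrix_from_weights(weights: dict, diet: str = "western") -> InteractionMatrix:
    """InteractionMatrix from a {(target, source): w} dict."""
    return InteractionMatrix(diet=diet, weights=dict(weights))


def network_from_edges(edges, nodes=None) -> DependencyNetwork:
    """DependencyNetwork from (source, target, signed_w) triples."""
    G = nx.DiGraph()
    if nodes:
        G.add_nodes_from(nodes)
    for source, target, w in edges:
        G.add_edge(
            source, target, signed_w=float(w), magnitude=float(abs(w)),
            sign="promoting" if w > 0 else "inhibiting",
        )
    return DependencyNetwork(graph=G, condition="control", diet="western", threshold=0.0)


def random_matrix(rng: np.random.Generator, n: int, scale: float = 3.0,
                  diet: str = "western") -> InteractionMatrix:
    """Complete random interaction matrix over n species."""
    species = [f"s{i:02d}" for i in range(n)]
    weights = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            weights[(a, b)] = float(rng.normal(0, scale))
            weights[(b, a)] = float(rng.normal(0, scale))
    return InteractionMatrix(diet=diet, weights=weights)
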