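"""Metabolic dependency networks: construction, communities, centrality.

Nodes are selected species; a directed edge source -> target exists when
the magnitude of the target's log2 growth change caused by the source
exceeds a threshold (|w| > 4 in the source analysis).  Edge direction
runs influencer -> influenced, so inbound links mean "being influenced".
Community structure is found by modularity maximization on the
undirected magnitude-weighted projection; node importance by PageRank on
the directed magnitude-weighted graph.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import (
    CONTROL,
    AbundanceTable,
    GutnetError,
    TaxonClassification,
    UNCLASSIFIED,
    ValidationError,
)
from .weights import InteractionMatrix

PROMOTING = "promoting"
INHIBITING = "inhibiting"

DEFAULT_THRESHOLD = 4.0


class ConvergenceError(GutnetError):
    """Iterative solver failed to converge within its iteration budget."""


@dataclass
class DependencyNetwork:
    """A directed, weighted dependency graph for one condition and diet.

    Node attributes: ``species_class``, ``abundance`` (mean relative
    abundance in the condition, as a fraction).  Edge attributes:
    ``signed_w`` (log2 units), ``magnitude`` (|signed_w|), ``sign``
    (promoting/inhibiting).
    """

    graph: nx.DiGraph
    condition: str = CONTROL
    diet: str = ""
    threshold: float = DEFAULT_THRESHOLD
    dropped: tuple = ()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_network(
    matrix: InteractionMatrix,
    nodes: Iterable[str],
    abundance: AbundanceTable | None = None,
    classes: TaxonClassification | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    condition: str = CONTROL,
) -> DependencyNetwork:
    """Build the dependency network over a species set.

    An edge source -> target is created iff |w(target<-source)| >
    ``threshold`` (strict).  Isolated nodes are retained.  Requested
    nodes absent from the matrix are dropped with a warning and listed in
    ``DependencyNetwork.dropped``.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    requested = sorted(set(nodes))
    organisms = matrix.organisms
    kept = [n for n in requested if n in organisms]
    dropped = tuple(n for n in requested if n not in organisms)
    if dropped:
        warnings.warn(
            f"{len(dropped)} requested node(s) absent from the interaction "
            f"matrix and dropped: {list(dropped)}",
            stacklevel=2,
        )
    mean_ab = abundance.mean_abundance(condition) if abundance is not None else None
    G = nx.DiGraph()
    for n in kept:
        G.add_node(
            n,
            species_class=classes.class_of(n) if classes is not None else UNCLASSIFIED,
            abundance=float(mean_ab.get(n, 0.0)) if mean_ab is not None else 0.0,
        )
    kept_set = set(kept)
    for (target, source), w in matrix.items():
        if source in kept_set and target in kept_set and abs(w) > threshold:
            G.add_edge(
                source,
                target,
                signed_w=float(w),
                magnitude=float(abs(w)),
                sign=PROMOTING if w > 0 else INHIBITING,
            )
    return DependencyNetwork(
        graph=G,
        condition=condition,
        diet=matrix.diet,
        threshold=float(threshold),
        dropped=dropped,
    )


def undirected_projection(network: DependencyNetwork) -> nx.Graph:
    """Undirected projection with summed directed edge magnitudes."""
    U = nx.Graph()
    U.add_nodes_from(network.graph.nodes)
    for u, v, data in network.graph.edges(data=True):
        if U.has_edge(u, v):
            U[u][v]["weight"] += data["magnitude"]
        else:
            U.add_edge(u, v, weight=data["magnitude"])
    return U


@dataclass(frozen=True)
class CommunityPartition:
    membership: dict  # node -> community id (0-based, ordered by smallest member)
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[frozenset]:
        groups: dict[int, set] = {}
        for node, cid in self.membership.items():
            groups.setdefault(cid, set()).add(node)
        return [frozenset(groups[cid]) for cid in sorted(groups)]


def detect_communities(
    network: DependencyNetwork, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Louvain modularity communities on the undirected projection.

    Deterministic given ``seed``.  An edgeless network yields one
    singleton community per node with modularity 0.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValidationError("cannot detect communities on an empty network")
    U = undirected_projection(network)
    if U.number_of_edges() == 0:
        membership = {n: i for i, n in enumerate(sorted(U.nodes))}
        return CommunityPartition(membership=membership, modularity=0.0)
    comms = nx.community.louvain_communities(
        U, weight="weight", resolution=resolution, seed=seed
    )
    # stable ids: communities ordered by their lexicographically smallest node
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {node: cid for cid, comm in enumerate(comms) for node in comm}
    score = nx.community.modularity(
        U, [set(c) for c in comms], weight="weight", resolution=resolution
    )
    return CommunityPartition(membership=membership, modularity=float(score))


@dataclass(frozen=True)
class CentralityReport:
    scores: dict  # node -> pagerank score, sums to 1
    ranked: tuple  # nodes sorted by descending score, ties by id
    n_iter: int


def pagerank(
    network: DependencyNetwork,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CentralityReport:
    """PageRank by dense power iteration on edge magnitudes.

    Out-weights are normalized per node; dangling nodes redistribute
    their mass uniformly.  Convergence is declared when the L1 change of
    the score vector drops below ``tol``.
    """
    if not 0 < damping < 1:
        raise ValidationError(f"damping must be in (0,1), got {damping}")
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("cannot rank an empty network")
    index = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in network.graph.edges(data=True):
        M[index[v], index[u]] = data["magnitude"]
    out = M.sum(axis=0)
    dangling = out == 0
    M[:, ~dangling] /= out[~dangling]
    M[:, dangling] = 1.0 / n
    x = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        x_new = damping * (M @ x) + (1.0 - damping) / n
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(last L1 residual {residual:.3e})"
        )
    scores = {node: float(x[index[node]]) for node in nodes}
    ranked = tuple(sorted(nodes, key=lambda nd: (-scores[nd], nd)))
    return CentralityReport(scores=scores, ranked=ranked, n_iter=it)


def top_class_composition(
    report: CentralityReport, classes: TaxonClassification, k: int
) -> dict:
    """Species-class counts among the top-k PageRank nodes."""
    if k > len(report.ranked):
        raise ValidationError(
            f"k={k} exceeds node count {len(report.ranked)}"
        )
    counts = Counter(classes.class_of(node) for node in report.ranked[:k])
    return dict(counts)
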