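import networkx as nx
import numpy as np
import pytest

from gutnet import (
    TaxonClassification,
    ValidationError,
    build_network,
    detect_communities,
    pagerank,
    top_class_composition,
)
from gutnet.network import undirected_projection

from conftest import make_abundance, matrix_from_weights, network_from_edges, random_matrix


def solve_pagerank_exact(network, damping=0.85):
    """Independent oracle: solve (I - d M) r = (1-d)/n as a linear system."""
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in network.graph.edges(data=True):
        M[index[v], index[u]] = data["magnitude"]
    out = M.sum(axis=0)
    for j in range(n):
        if out[j] == 0:
            M[:, j] = 1.0 / n
        else:
            M[:, j] /= out[j]
    r = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1 - damping) / n))
    return {node: r[index[node]] for node in nodes}


class TestBuildNetwork:
    def test_threshold_keeps_single_direction(self):
        matrix = matrix_from_weights({("a", "b"): 5.0, ("b", "a"): 1.0})
        net = build_network(matrix, ["a", "b"], threshold=4.0)
        assert list(net.graph.edges) == [("b", "a")]
        assert net.graph.edges["b", "a"]["sign"] == "promoting"
        assert net.graph.edges["b", "a"]["signed_w"] == 5.0

    def test_all_subthreshold_gives_edgeless_network(self):
        matrix = matrix_from_weights({("a", "b"): 3.0, ("b", "a"): -4.0})
        net = build_network(matrix, ["a", "b"], threshold=4.0)
        assert net.graph.number_of_edges() == 0
        assert set(net.graph.nodes) == {"a", "b"}  # isolated nodes retained

    def test_edges_match_exhaustive_filter(self):
        rng = np.random.default_rng(17)
        matrix = random_matrix(rng, 10, scale=4.0)
        net = build_network(matrix, matrix.organisms, threshold=4.0)
        expected = {
            (source, target)
            for (target, source), w in matrix.items()
            if abs(w) > 4.0
        }
        assert set(net.graph.edges) == expected
        for (target, source), w in matrix.items():
            if (source, target) in expected:
                data = net.graph.edges[source, target]
                assert data["signed_w"] == pytest.approx(w)
                assert data["sign"] == ("promoting" if w > 0 else "inhibiting")

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(23)
        matrix = random_matrix(rng, 8, scale=4.0)
        lo = build_network(matrix, matrix.organisms, threshold=2.0)
        hi = build_network(matrix, matrix.organisms, threshold=5.0)
        assert set(hi.graph.edges) <= set(lo.graph.edges)

    def test_unknown_nodes_dropped_with_warning(self):
        matrix = matrix_from_weights({("a", "b"): 5.0, ("b", "a"): 1.0})
        with pytest.warns(UserWarning, match="dropped"):
            net = build_network(matrix, ["a", "b", "ghost"], threshold=4.0)
        assert net.dropped == ("ghost",)
        assert "ghost" not in net.graph

    def test_node_attributes_attached(self):
        matrix = matrix_from_weights({("a", "b"): 5.0, ("b", "a"): 1.0})
        table = make_abundance({"a": [0.2, 0.2, 0.4, 0.4], "b": [0.1, 0.1, 0.3, 0.3]}, 2, 2)
        classes = TaxonClassification({"a": "probiotic", "b": "commensal"})
        net = build_network(matrix, ["a", "b"], table, classes, 4.0, condition="patient")
        assert net.graph.nodes["a"]["species_class"] == "probiotic"
        assert net.graph.nodes["a"]["abundance"] == pytest.approx(0.2)


class TestCommunities:
    @staticmethod
    def two_block_network(block_a, block_b, within=6.0, bridge=None):
        edges = []
        for block in (block_a, block_b):
            for i, u in enumerate(block):
                for v in block[i + 1:]:
                    edges.append((u, v, within))
                    edges.append((v, u, -within))
        if bridge:
            edges.append((*bridge, 0.5))
        return network_from_edges(edges)

    def test_two_cliques_recovered(self):
        net = self.two_block_network(
            ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"],
            bridge=("a1", "b1"),
        )
        part = detect_communities(net)
        assert part.n_communities == 2
        comms = part.communities()
        assert frozenset(["a1", "a2", "a3", "a4"]) in comms

    def test_single_clique_is_one_community(self):
        net = self.two_block_network(["x1", "x2", "x3", "x4"], [])
        part = detect_communities(net)
        assert part.n_communities == 1

    def test_planted_partition_modularity_closed_form(self):
        """Two equal-weight disconnected blocks have modularity exactly 1/2."""
        net = self.two_block_network(
            [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]
        )
        part = detect_communities(net)
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5)
        blocks = {frozenset(f"a{i}" for i in range(6)), frozenset(f"b{i}" for i in range(6))}
        assert set(part.communities()) == blocks

    def test_edgeless_network_singletons(self):
        net = network_from_edges([], nodes=["a", "b", "c"])
        part = detect_communities(net)
        assert part.n_communities == 3
        assert part.modularity == 0.0

    def test_partition_beats_trivial_partition(self):
        rng = np.random.default_rng(31)
        matrix = random_matrix(rng, 12, scale=4.0)
        net = build_network(matrix, matrix.organisms, threshold=3.0)
        part = detect_communities(net)
        U = undirected_projection(net)
        if U.number_of_edges():
            trivial = nx.community.modularity(U, [set(U.nodes)], weight="weight")
            assert part.modularity >= trivial - 1e-12

    def test_scale_invariance(self):
        net = self.two_block_network(["a1", "a2", "a3"], ["b1", "b2", "b3"],
                                     bridge=("a1", "b1"))
        scaled = network_from_edges(
            [(u, v, d["signed_w"] * 7) for u, v, d in net.graph.edges(data=True)]
        )
        assert detect_communities(net).membership == detect_communities(scaled).membership


class TestPageRank:
    def test_single_node_scores_one(self):
        net = network_from_edges([], nodes=["only"])
        report = pagerank(net)
        assert report.scores["only"] == pytest.approx(1.0)

    def test_symmetric_ring_is_uniform(self):
        n = 8
        edges = [(f"n{i}", f"n{(i + 1) % n}", 2.5) for i in range(n)]
        edges += [(f"n{(i + 1) % n}", f"n{i}", 2.5) for i in range(n)]
        report = pagerank(network_from_edges(edges))
        for score in report.scores.values():
            assert score == pytest.approx(1.0 / n, abs=1e-9)

    def test_scores_sum_to_one_and_positive(self):
        rng = np.random.default_rng(41)
        matrix = random_matrix(rng, 15, scale=4.0)
        net = build_network(matrix, matrix.organisms, threshold=3.0)
        report = pagerank(net)
        assert sum(report.scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(s > 0 for s in report.scores.values())

    def test_matches_linear_solve_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            n = int(rng.integers(6, 21))
            edges = []
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.3:
                        edges.append((f"v{i}", f"v{j}", float(rng.uniform(0.5, 8))))
            net = network_from_edges(edges, nodes=[f"v{i}" for i in range(n)])
            report = pagerank(net, tol=1e-13)
            exact = solve_pagerank_exact(net)
            for node in exact:
                assert report.scores[node] == pytest.approx(exact[node], abs=1e-8)

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(47)
        matrix = random_matrix(rng, 10, scale=4.0)
        net = build_network(matrix, matrix.organisms, threshold=2.0)
        report = pagerank(net, tol=1e-13)
        ref = nx.pagerank(net.graph, alpha=0.85, weight="magnitude", tol=1e-12)
        for node in ref:
            assert report.scores[node] == pytest.approx(ref[node], abs=1e-7)

    def test_scaling_magnitudes_leaves_scores(self):
        edges = [("a", "b", 5.0), ("b", "c", -6.0), ("c", "a", 4.5), ("a", "c", -7.0)]
        scaled = [(u, v, w * 3) for u, v, w in edges]
        r1 = pagerank(network_from_edges(edges))
        r2 = pagerank(network_from_edges(scaled))
        for node in r1.scores:
            assert r1.scores[node] == pytest.approx(r2.scores[node], abs=1e-9)


class TestTopClassComposition:
    def test_uniform_class(self):
        net = network_from_edges([], nodes=[f"p{i}" for i in range(5)])
        classes = TaxonClassification({f"p{i}": "probiotic" for i in range(5)})
        report = pagerank(net)
        assert top_class_composition(report, classes, 5) == {"probiotic": 5}

    def test_alternating_classes_split(self):
        nodes = ["a", "b", "c", "d"]
        classes = TaxonClassification(
            {"a": "probiotic", "b": "commensal", "c": "probiotic", "d": "commensal"}
        )
        report = pagerank(network_from_edges([], nodes=nodes))
        assert top_class_composition(report, classes, 4) == {"probiotic": 2, "commensal": 2}

    def test_k_beyond_node_count_rejected(self):
        report = pagerank(network_from_edges([], nodes=["a"]))
        with pytest.raises(ValidationError):
            top_class_composition(report, TaxonClassification({}), 2)

    def test_heavy_inbound_probiotics_overrepresented(self):
        """Probiotics receiving the heaviest inbound edges dominate the top-k."""
        rng = np.random.default_rng(53)
        probiotics = [f"p{i}" for i in range(4)]
        others = [f"o{i}" for i in range(16)]
        edges = []
        for p in probiotics:
            for o in others:
                edges.append((o, p, 8.0))
        for i, o in enumerate(others):
            edges.append((others[(i + 1) % len(others)], o, float(rng.uniform(0.1, 0.5))))
        classes = TaxonClassification(
            {**{p: "probiotic" for p in probiotics}, **{o: "commensal" for o in others}}
        )
        report = pagerank(network_from_edges(edges))
        comp = top_class_composition(report, classes, 5)
        base_rate = len(probiotics) / (len(probiotics) + len(others))
        assert comp.get("probiotic", 0) / 5 > base_rate
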